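"""Reduce split-read evidence to a canonical signature and classify it.

Every junction is first *canonicalised* so that a read and its reverse
complement describe the same event identically: the two ends are ordered by
reference coordinate and, if the first end then maps to the reverse strand,
both strands are complemented.  Canonical junctions that share end sides,
chromosomes and (to within the clustering window) positions form a
*junction class*; the set of classes, their relative read proportions and
the number of distinct end loci (columns) make up the :class:`Signature`.

A small decision table maps signatures onto rearrangement types:

========================  =================================================
observed classes          call
========================  =================================================
1 class, same chrom,      deletion (junction skips forward along the
equal strands,            reference)
left->right, gap > 0
1 class, same chrom,      tandem duplication, with ring chromosome as an
equal strands,            unresolvable alternative: both events join a
right<-left (reversed)    span's end back to its start
2 mirrored classes,       inversion (both breakpoints joined with a strand
opposite strands          flip)
2 reciprocal cross-chrom  balanced translocation
classes
1 cross-chrom class       unbalanced translocation
2 classes sharing one     insertion of a distant origin span (inverted when
locus, distal origin      the strands disagree)
span
2 classes with distinct   complex insertion-deletion: origin span inserted
site flanks               with sequence loss at the site; when the origin is
                          on the same chromosome and inverted this is
                          indistinguishable from an offset inversion, which
                          is reported as an alternative
anything else             unclassified (never an exception)
========================  =================================================
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import NamedTuple

from .breakpoints import (DEFAULT_WINDOW, LEFT, RIGHT, ColumnSet, Junction,
                          extract_junctions, median_low)
from .errors import ClassificationError

MIN_CLASS_READS = 2       # reads needed for a pattern to enter the decision
MIN_CLASS_PROPORTION = 0.10   # minority patterns below this are ignored


class RearrangementType(str, enum.Enum):
    DELETION = "deletion"
    INSERTION = "insertion"
    INVERSION = "inversion"
    TANDEM_DUPLICATION = "tandem_duplication"
    TRANSLOCATION_BALANCED = "translocation_balanced"
    TRANSLOCATION_UNBALANCED = "translocation_unbalanced"
    RING_CHROMOSOME = "ring_chromosome"
    COMPLEX_INSERTION_DELETION = "complex_insertion_deletion"
    UNCLASSIFIED = "unclassified"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class End(NamedTuple):
    chrom: str
    pos: int
    side: str
    strand: str


def _flip(end: End) -> End:
    return end._replace(strand="-" if end.strand == "+" else "+")


def canonicalize_junction(j: Junction) -> tuple[End, End]:
    """Orientation-independent form of a junction.

    Ends are sorted by (chrom, pos, side); if the first end's strand is '-'
    both strands are complemented, which is what reading the same molecule
    from the other direction does.
    """
    a = End(*j.a)
    b = End(*j.b)
    if (b.chrom, b.pos, b.side) < (a.chrom, a.pos, a.side):
        a, b = b, a
    if a.strand == "-":
        a, b = _flip(a), _flip(b)
    return a, b


@dataclass
class JunctionClass:
    """Junctions sharing a canonical shape and (fuzzy) end positions."""

    a_chrom: str
    a_side: str
    b_chrom: str
    b_side: str
    strands_equal: bool
    a_strand: str
    b_strand: str
    members: list[tuple[str, int, int]] = field(default_factory=list)
    # members: (read_id, a_pos, b_pos)

    @property
    def a_pos(self) -> int:
        return median_low([m[1] for m in self.members])

    @property
    def b_pos(self) -> int:
        return median_low([m[2] for m in self.members])

    @property
    def read_ids(self) -> set[str]:
        return {m[0] for m in self.members}

    @property
    def support(self) -> int:
        return len(self.read_ids)

    @property
    def same_chrom(self) -> bool:
        return self.a_chrom == self.b_chrom

    @property
    def endpoints(self) -> tuple[End, End]:
        return (End(self.a_chrom, self.a_pos, self.a_side, self.a_strand),
                End(self.b_chrom, self.b_pos, self.b_side, self.b_strand))

    def pattern_key(self) -> tuple:
        gap = self.b_pos - self.a_pos if self.same_chrom else None
        order = ("zero" if gap == 0 else "positive" if gap and gap > 0
                 else "negative") if gap is not None else "cross"
        return (self.a_chrom, self.a_side, self.a_strand,
                self.b_chrom, self.b_side, self.b_strand,
                self.strands_equal, order)


@dataclass
class Signature:
    """Deterministic summary of the split-read evidence for one event."""

    classes: list[JunctionClass]
    n_columns: int
    n_reads: int
    n_excluded: int
    window: int = DEFAULT_WINDOW

    @property
    def pattern_proportions(self) -> dict[tuple, float]:
        total = sum(c.support for c in self.classes)
        return {c.pattern_key(): c.support / total for c in self.classes}

    def canonical_json(self) -> str:
        """Serialisation of the evidence *pattern*, independent of depth.

        Two event types that produce the same arrangement of split-read
        alignments (ring chromosome vs tandem duplication; offset inversion
        vs inverted same-chromosome insertion-deletion) serialise
        identically, which is how provable ambiguity is asserted.
        """
        payload = {
            "n_columns": self.n_columns,
            "classes": [
                {
                    "a": [c.a_chrom, c.a_pos, c.a_side, c.a_strand],
                    "b": [c.b_chrom, c.b_pos, c.b_side, c.b_strand],
                    "strands_equal": c.strands_equal,
                }
                for c in self.classes
            ],
        }
        return json.dumps(payload, sort_keys=True, separators=(",", ":"))


def _near(a: int, b: int, window: int) -> bool:
    return abs(a - b) <= window


def compute_signature(reads, breakpoints=None,
                      window: int = DEFAULT_WINDOW) -> Signature:
    """Scan selected split reads and group their junctions into classes.

    ``breakpoints`` restricts the analysis: a junction is used only when
    both of its ends fall within ``window`` of a given breakpoint locus
    (clusters, columns, or bare ``(chrom, pos)`` pairs).  Reads
    contributing no usable junction are excluded and counted.  The result
    is independent of read order.
    """
    loci = None
    if breakpoints is not None:
        loci = []
        for bp in breakpoints:
            if isinstance(bp, tuple):
                loci.append(bp)
            else:  # BreakpointCluster or Column
                loci.append((bp.chrom, bp.position))

    def matches(end: End) -> bool:
        if loci is None:
            return True
        return any(end.chrom == c and _near(end.pos, p, window)
                   for c, p in loci)

    kept: list[tuple[str, End, End]] = []
    used_reads: set[str] = set()
    n_excluded = 0
    for read in sorted(reads, key=lambda r: r.read_id):
        if not read.is_split or not read.consistent:
            n_excluded += 1
            continue
        any_kept = False
        for j in extract_junctions(read):
            a, b = canonicalize_junction(j)
            if matches(a) and matches(b):
                kept.append((read.read_id, a, b))
                any_kept = True
        if any_kept:
            used_reads.add(read.read_id)
        else:
            n_excluded += 1
    if not used_reads:
        raise ClassificationError("no selected read carries a junction "
                                  "matching the given breakpoints")

    # group by shape, then single-linkage on positions within each shape
    shapes: dict[tuple, list[tuple[str, End, End]]] = {}
    for rid, a, b in kept:
        key = (a.chrom, a.side, b.chrom, b.side,
               a.strand == b.strand, a.strand, b.strand)
        shapes.setdefault(key, []).append((rid, a, b))

    classes: list[JunctionClass] = []
    for key in sorted(shapes):
        entries = sorted(shapes[key], key=lambda e: (e[1].pos, e[2].pos))
        run: list[tuple[str, End, End]] = []
        for entry in entries:
            if run and not (_near(entry[1].pos, run[-1][1].pos, window)
                            and _near(entry[2].pos, run[-1][2].pos, window)):
                classes.append(_make_class(key, run))
                run = []
            run.append(entry)
        classes.append(_make_class(key, run))
    classes.sort(key=lambda c: (c.a_chrom, c.a_pos, c.b_chrom, c.b_pos,
                                c.a_side, c.b_side))

    n_columns = _count_columns(classes, window)
    return Signature(classes, n_columns, len(used_reads), n_excluded, window)


def _make_class(key: tuple, run: list[tuple[str, End, End]]) -> JunctionClass:
    a_chrom, a_side, b_chrom, b_side, eq, a_strand, b_strand = key
    return JunctionClass(
        a_chrom, a_side, b_chrom, b_side, eq, a_strand, b_strand,
        members=[(rid, a.pos, b.pos) for rid, a, b in run])


def _count_columns(classes: list[JunctionClass], window: int) -> int:
    """Distinct end loci after merging within the window, per chromosome."""
    per_chrom: dict[str, list[int]] = {}
    for c in classes:
        for end in c.endpoints:
            per_chrom.setdefault(end.chrom, []).append(end.pos)
    n = 0
    for chrom in per_chrom:
        positions = sorted(per_chrom[chrom])
        n += 1
        for prev, cur in zip(positions, positions[1:]):
            if cur - prev > window:
                n += 1
    return n


@dataclass
class Classification:
    rtype: RearrangementType
    alternatives: list[RearrangementType]
    details: dict = field(default_factory=dict)


def classify_signature(sig: Signature,
                       window: int | None = None) -> Classification:
    """Map a signature to a rearrangement type; total over valid input."""
    window = sig.window if window is None else window
    total_reads = sum(c.support for c in sig.classes) or 1
    classes = [c for c in sig.classes
               if c.support >= MIN_CLASS_READS
               and c.support / total_reads >= MIN_CLASS_PROPORTION]
    if not classes:
        return Classification(RearrangementType.UNCLASSIFIED, [],
                              {"reason": "no adequately supported pattern"})
    if len(classes) == 1:
        return _classify_single(classes[0])
    if len(classes) == 2:
        return _classify_pair(classes[0], classes[1], window)
    return Classification(
        RearrangementType.UNCLASSIFIED, [],
        {"reason": f"{len(classes)} junction patterns; very complex event — "
                   "manual review suggested"})


def _classify_single(c: JunctionClass) -> Classification:
    details = {"classes": [c]}
    if not c.same_chrom:
        return Classification(
            RearrangementType.TRANSLOCATION_UNBALANCED, [], details)
    if c.strands_equal:
        if (c.a_side, c.b_side) == (LEFT, RIGHT) and c.a_pos < c.b_pos:
            return Classification(RearrangementType.DELETION, [], details)
        if (c.a_side, c.b_side) == (RIGHT, LEFT):
            # the end of a span joined back to its start: a tandem
            # duplication and a ring chromosome are indistinguishable here
            return Classification(
                RearrangementType.TANDEM_DUPLICATION,
                [RearrangementType.RING_CHROMOSOME], details)
    return Classification(
        RearrangementType.UNCLASSIFIED, [],
        {"reason": "single junction pattern matches no simple event",
         "classes": [c]})


def _reciprocal(c1: JunctionClass, c2: JunctionClass, window: int) -> bool:
    """Same two loci joined in both derivative orientations."""
    (a1, b1), (a2, b2) = c1.endpoints, c2.endpoints
    if (a1.chrom, b1.chrom) != (a2.chrom, b2.chrom):
        return False
    if not (_near(a1.pos, a2.pos, window) and _near(b1.pos, b2.pos, window)):
        return False
    return a1.side != a2.side and b1.side != b2.side


def _mirrored_inversion(c1: JunctionClass, c2: JunctionClass,
                        window: int) -> bool:
    """Both breakpoints joined with a strand flip at the same two loci."""
    if c1.strands_equal or c2.strands_equal:
        return False
    if not (c1.same_chrom and c2.same_chrom
            and c1.a_chrom == c2.a_chrom):
        return False
    sides = {(c1.a_side, c1.b_side), (c2.a_side, c2.b_side)}
    if sides != {(LEFT, LEFT), (RIGHT, RIGHT)}:
        return False
    return (_near(c1.a_pos, c2.a_pos, window)
            and _near(c1.b_pos, c2.b_pos, window))


def partition_endpoints(c1: JunctionClass, c2: JunctionClass,
                        window: int) -> dict | None:
    """Try to read two junction classes as one insertion event.

    Seeks an *insertion site* pair — a left end from one class and a right
    end from the other on a common chromosome — whose gap is the sequence
    lost at the site, with the two remaining ends delimiting the *origin*
    span that was copied in.  When several partitions are geometrically
    consistent (the offset-inversion situation) the one with the smallest
    loss is reported; the ambiguity itself is flagged by the caller.
    """
    ends = [(0, e) for e in c1.endpoints] + [(1, e) for e in c2.endpoints]
    candidates = []
    for i, (src_l, l_end) in enumerate(ends):
        if l_end.side != LEFT:
            continue
        for k, (src_r, r_end) in enumerate(ends):
            if r_end.side != RIGHT or src_r == src_l:
                continue
            if l_end.chrom != r_end.chrom:
                continue
            if r_end.pos < l_end.pos - window:
                continue
            rest = [ends[m][1] for m in range(4) if m not in (i, k)]
            lo, hi = sorted(rest, key=lambda e: (e.chrom, e.pos))
            if lo.chrom != hi.chrom:
                continue
            if not (lo.side == RIGHT and hi.side == LEFT and lo.pos < hi.pos):
                continue
            loss = max(0, r_end.pos - l_end.pos)
            candidates.append({
                "site_chrom": l_end.chrom,
                "site_left": l_end.pos,
                "site_right": r_end.pos,
                "loss": loss,
                "origin_chrom": lo.chrom,
                "origin_start": lo.pos,
                "origin_end": hi.pos,
            })
    if not candidates:
        return None
    candidates.sort(key=lambda c: (c["loss"], c["site_left"],
                                   c["origin_start"]))
    chosen = dict(candidates[0])
    chosen["n_partitions"] = len(candidates)
    return chosen


def _classify_pair(c1: JunctionClass, c2: JunctionClass,
                   window: int) -> Classification:
    details: dict = {"classes": [c1, c2]}
    if not c1.same_chrom and not c2.same_chrom:
        if _reciprocal(c1, c2, window):
            return Classification(
                RearrangementType.TRANSLOCATION_BALANCED, [], details)
    if _mirrored_inversion(c1, c2, window):
        return Classification(RearrangementType.INVERSION, [], details)
    part = partition_endpoints(c1, c2, window)
    if part is not None:
        details.update(part)
        inverted = not (c1.strands_equal and c2.strands_equal)
        details["inverted"] = inverted
        if part["site_right"] - part["site_left"] <= window:
            return Classification(RearrangementType.INSERTION, [], details)
        alternatives = []
        if inverted and part["origin_chrom"] == part["site_chrom"]:
            # inverted insertion-deletion on one chromosome cannot be told
            # apart from an offset inversion
            alternatives.append(RearrangementType.INVERSION)
        return Classification(
            RearrangementType.COMPLEX_INSERTION_DELETION, alternatives,
            details)
    return Classification(
        RearrangementType.UNCLASSIFIED, [],
        {"reason": "two junction patterns admit no consistent event",
         "classes": [c1, c2]})


@dataclass
class ComplexityAssessment:
    label: str              # "simple" | "complex"
    warning: str | None = None


def assess_complexity(columns: ColumnSet) -> ComplexityAssessment:
    """Column-count heuristic separating the two annotation workflows."""
    n = columns.n_columns
    if n == 0:
        raise ClassificationError("no columns to assess")
    if n <= 2:
        return ComplexityAssessment("simple")
    if n == 3 and _has_insertion_topology(columns):
        return ComplexityAssessment("simple")
    if n > 4:
        return ComplexityAssessment(
            "complex", "more than 4 columns: very complex locus, manual "
                       "review recommended")
    return ComplexityAssessment("complex")


def _has_insertion_topology(columns: ColumnSet) -> bool:
    """One column carries both junction sides and pairs with the others."""
    for i, col in enumerate(columns.columns):
        if {LEFT, RIGHT} <= col.sides:
            linked = {tuple(sorted(p)) for p in columns.pairing}
            others = set(range(columns.n_columns)) - {i}
            if all(tuple(sorted((i, o))) in linked for o in others):
                return True
    return False
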