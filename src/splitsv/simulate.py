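"""Rearranged-genome simulator with exact ground truth.

Applies a specified structural rearrangement to a reference, tiles the
rearranged sequence with deterministic faux reads (10 kb windows every
1 kb, alternating orientations), and — because every read's provenance is
known exactly — constructs the alignments a perfect aligner would report,
written as a coordinate-sorted, indexed truth BAM with consistent primary/
supplementary records and SA tags.  This makes the whole detection →
classification → annotation pipeline testable hermetically, with no
external aligner or download.

The per-contig :class:`CoordinateMap` is the formal ground truth: an
ordered list of reference pieces (with orientation) whose concatenation is
the rearranged sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pysam

from .classify import RearrangementType
from .errors import SpecError

DEFAULT_READ_LEN = 10_000
DEFAULT_STEP = 1_000
TRUTH_MAPQ = 60

_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


# ---------------------------------------------------------------------------
# reference

DEFAULT_CHROM_LENGTHS = {"chrA": 600_000, "chrB": 450_000}
_REFERENCE_SEED = 20177  # fixed: the bundled reference is a constant


def synthetic_reference(chrom_lengths: dict[str, int] | None = None,
                        ) -> dict[str, str]:
    """Deterministic random reference with soft low-complexity patches.

    The reference is a substrate, not part of the method; a fixed internal
    seed makes the whole scenario catalogue byte-reproducible.
    """
    chrom_lengths = chrom_lengths or DEFAULT_CHROM_LENGTHS
    rng = np.random.default_rng(_REFERENCE_SEED)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = {}
    for chrom in sorted(chrom_lengths):
        n = chrom_lengths[chrom]
        arr = bases[rng.integers(0, 4, n)]
        # sprinkle short dinucleotide-repeat patches
        for start in range(75_000, n - 400, 150_000):
            pat = np.frombuffer(b"AT" * 200, dtype=np.uint8)
            arr[start:start + 400] = pat
        out[chrom] = arr.tobytes().decode()
    return out


# ---------------------------------------------------------------------------
# specifications

@dataclass(frozen=True)
class RearrangementSpec:
    """One rearrangement to apply to the reference.

    Field usage by kind (all coordinates 0-based half-open):

    - deletion / inversion / tandem_duplication / ring_chromosome:
      ``chrom``, ``start``, ``end`` (for a ring, the retained span).
    - insertion: origin span (``origin_chrom``, ``origin_start``,
      ``origin_end``, ``inverted``) copied to ``chrom`` at
      ``insertion_point``.
    - complex_insertion_deletion: as insertion, plus loss of
      ``[insertion_point, loss_end)`` at the site.
    - translocation: arms swapped between ``chrom`` at ``start`` and
      ``chrom2`` at ``pos2``; ``derivative`` selects which derivative
      chromosomes the reads come from ("both" = balanced).
    """

    identifier: str
    kind: RearrangementType
    chrom: str
    start: int = 0
    end: int = 0
    origin_chrom: str | None = None
    origin_start: int | None = None
    origin_end: int | None = None
    insertion_point: int | None = None
    loss_end: int | None = None
    inverted: bool = False
    chrom2: str | None = None
    pos2: int | None = None
    derivative: str = "both"

    @property
    def ambiguity_class(self) -> str | None:
        """Which provably ambiguous signature class, if any, this produces."""
        if self.kind in (RearrangementType.TANDEM_DUPLICATION,
                         RearrangementType.RING_CHROMOSOME):
            return "ring_vs_tandem_duplication"
        if (self.kind == RearrangementType.COMPLEX_INSERTION_DELETION
                and self.inverted and self.origin_chrom == self.chrom):
            return "offset_inversion_vs_inverted_insertion_deletion"
        return None

    def truth_breakpoints(self) -> set[tuple[str, int]]:
        k = self.kind
        if k in (RearrangementType.DELETION, RearrangementType.INVERSION,
                 RearrangementType.TANDEM_DUPLICATION,
                 RearrangementType.RING_CHROMOSOME):
            return {(self.chrom, self.start), (self.chrom, self.end)}
        if k == RearrangementType.INSERTION:
            return {(self.chrom, self.insertion_point),
                    (self.origin_chrom, self.origin_start),
                    (self.origin_chrom, self.origin_end)}
        if k == RearrangementType.COMPLEX_INSERTION_DELETION:
            return {(self.chrom, self.insertion_point),
                    (self.chrom, self.loss_end),
                    (self.origin_chrom, self.origin_start),
                    (self.origin_chrom, self.origin_end)}
        if k in (RearrangementType.TRANSLOCATION_BALANCED,
                 RearrangementType.TRANSLOCATION_UNBALANCED):
            return {(self.chrom, self.start), (self.chrom2, self.pos2)}
        raise SpecError(f"no truth breakpoints for kind {k}")

    def expected_type(self) -> RearrangementType:
        """Primary call expected from error-free evidence.

        A ring chromosome presents the duplication-like signature, so the
        primary call is tandem_duplication with ring as the alternative.
        """
        if self.kind == RearrangementType.RING_CHROMOSOME:
            return RearrangementType.TANDEM_DUPLICATION
        return self.kind


# ---------------------------------------------------------------------------
# coordinate maps and rearranged genomes

@dataclass(frozen=True)
class MapPiece:
    chrom: str
    start: int
    end: int
    orientation: str  # '+' | '-'

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CoordinateMap:
    """Piecewise provenance of a rearranged sequence."""

    pieces: list[MapPiece]
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.pieces:
            raise SpecError("a coordinate map needs at least one piece")

    @property
    def length(self) -> int:
        return sum(p.length for p in self.pieces)

    def materialize(self, reference: dict[str, str]) -> str:
        parts = []
        for p in self.pieces:
            seq = reference[p.chrom][p.start:p.end]
            parts.append(seq if p.orientation == "+" else revcomp(seq))
        return "".join(parts)


@dataclass
class RearrangedContig:
    name: str
    sequence: str
    cmap: CoordinateMap


@dataclass
class RearrangedGenome:
    spec: RearrangementSpec
    contigs: list[RearrangedContig]

    def truth_record(self) -> dict:
        spec = self.spec
        return {
            "identifier": spec.identifier,
            "kind": spec.kind.value,
            "expected_type": spec.expected_type().value,
            "ambiguity_class": spec.ambiguity_class,
            "breakpoints": sorted(spec.truth_breakpoints()),
            "contigs": [
                {"name": c.name, "length": len(c.sequence),
                 "circular": c.cmap.circular,
                 "pieces": [[p.chrom, p.start, p.end, p.orientation]
                            for p in c.cmap.pieces]}
                for c in self.contigs],
        }


def _check_span(reference: dict[str, str], chrom: str, start: int,
                end: int, what: str) -> None:
    if chrom not in reference:
        raise SpecError(f"{what}: unknown chromosome {chrom!r}")
    if not (0 <= start < end <= len(reference[chrom])):
        raise SpecError(f"{what}: span {chrom}:{start}-{end} outside "
                        f"reference bounds (length {len(reference[chrom])})")


def apply_rearrangement(reference: dict[str, str],
                        spec: RearrangementSpec) -> RearrangedGenome:
    """Apply one rearrangement; returns the affected contig(s) with maps."""
    k = spec.kind
    c = spec.chrom
    if k in (RearrangementType.DELETION, RearrangementType.INVERSION,
             RearrangementType.TANDEM_DUPLICATION,
             RearrangementType.RING_CHROMOSOME):
        _check_span(reference, c, spec.start, spec.end, spec.identifier)
        L = len(reference[c])
        s, e = spec.start, spec.end
        if k == RearrangementType.DELETION:
            pieces = [MapPiece(c, 0, s, "+"), MapPiece(c, e, L, "+")]
        elif k == RearrangementType.INVERSION:
            pieces = [MapPiece(c, 0, s, "+"), MapPiece(c, s, e, "-"),
                      MapPiece(c, e, L, "+")]
        elif k == RearrangementType.TANDEM_DUPLICATION:
            pieces = [MapPiece(c, 0, e, "+"), MapPiece(c, s, e, "+"),
                      MapPiece(c, e, L, "+")]
        else:  # ring: the retained span circularises; distal ends are lost
            cmap = CoordinateMap([MapPiece(c, s, e, "+")], circular=True)
            contig = RearrangedContig(f"{spec.identifier}|{c}",
                                      cmap.materialize(reference), cmap)
            return RearrangedGenome(spec, [contig])
        cmap = CoordinateMap(pieces)
        return RearrangedGenome(spec, [RearrangedContig(
            f"{spec.identifier}|{c}", cmap.materialize(reference), cmap)])

    if k in (RearrangementType.INSERTION,
             RearrangementType.COMPLEX_INSERTION_DELETION):
        _check_span(reference, spec.origin_chrom, spec.origin_start,
                    spec.origin_end, spec.identifier)
        p = spec.insertion_point
        q = spec.loss_end if k is RearrangementType.COMPLEX_INSERTION_DELETION \
            else p
        if p is None or not (0 < p <= q < len(reference[c])):
            raise SpecError(f"{spec.identifier}: bad insertion/loss "
                            f"coordinates p={p} q={q}")
        L = len(reference[c])
        pieces = [MapPiece(c, 0, p, "+"),
                  MapPiece(spec.origin_chrom, spec.origin_start,
                           spec.origin_end, "-" if spec.inverted else "+"),
                  MapPiece(c, q, L, "+")]
        cmap = CoordinateMap(pieces)
        return RearrangedGenome(spec, [RearrangedContig(
            f"{spec.identifier}|{c}", cmap.materialize(reference), cmap)])

    if k in (RearrangementType.TRANSLOCATION_BALANCED,
             RearrangementType.TRANSLOCATION_UNBALANCED):
        cA, pA, cB, pB = spec.chrom, spec.start, spec.chrom2, spec.pos2
        _check_span(reference, cA, 0, pA, spec.identifier)
        _check_span(reference, cB, 0, pB, spec.identifier)
        LA, LB = len(reference[cA]), len(reference[cB])
        der1 = CoordinateMap([MapPiece(cA, 0, pA, "+"),
                              MapPiece(cB, pB, LB, "+")])
        der2 = CoordinateMap([MapPiece(cB, 0, pB, "+"),
                              MapPiece(cA, pA, LA, "+")])
        contigs = []
        if spec.derivative in ("both", "der1"):
            contigs.append(RearrangedContig(
                f"{spec.identifier}|der1", der1.materialize(reference), der1))
        if spec.derivative in ("both", "der2"):
            contigs.append(RearrangedContig(
                f"{spec.identifier}|der2", der2.materialize(reference), der2))
        if not contigs:
            raise SpecError(f"{spec.identifier}: derivative must be "
                            "'both', 'der1' or 'der2'")
        return RearrangedGenome(spec, contigs)

    raise SpecError(f"unsupported rearrangement kind {k}")


# ---------------------------------------------------------------------------
# faux reads

@dataclass
class FauxRead:
    id: str
    sequence: str
    offset: int       # start on the rearranged sequence
    orientation: str  # '+' emitted as-is, '-' emitted reverse-complemented


@dataclass
class FauxReadSet:
    reads: list[FauxRead]
    read_len: int = DEFAULT_READ_LEN
    step: int = DEFAULT_STEP
    circular: bool = False


def make_faux_reads(sequence: str, read_len: int = DEFAULT_READ_LEN,
                    step: int = DEFAULT_STEP, circular: bool = False,
                    id_prefix: str = "read") -> FauxReadSet:
    """Tile a sequence with fixed-interval reads of alternating orientation.

    Reads start at 0, step, 2*step, ...; even-index reads are emitted
    forward, odd-index reads reverse-complemented.  On a linear sequence
    the tail windows are emitted truncated so coverage reaches the end; on
    a circular sequence windows wrap the junction.
    """
    if len(sequence) < 1:
        raise SpecError("cannot tile an empty sequence")
    reads = []
    n = len(sequence)
    doubled = sequence + sequence if circular else sequence
    for idx, offset in enumerate(range(0, n, step)):
        window = doubled[offset:offset + read_len]
        orientation = "+" if idx % 2 == 0 else "-"
        seq = window if orientation == "+" else revcomp(window)
        reads.append(FauxRead(f"{id_prefix}|r{idx:05d}", seq, offset,
                              orientation))
    return FauxReadSet(reads, read_len, step, circular)


def add_read_noise(read_set: FauxReadSet, sub_rate: float,
                   indel_rate: float, seed: int) -> FauxReadSet:
    """Reproducible base-level noise; ground truth records are unchanged.

    Substitutions always change the base, so the per-read mismatch count is
    exactly binomial(read length, sub_rate).
    """
    if not (0 <= sub_rate < 1 and 0 <= indel_rate < 1):
        raise SpecError("noise rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    alphabet = "ACGT"
    noisy = []
    for read in read_set.reads:
        seq = read.sequence
        n = len(seq)
        chars = list(seq)
        if sub_rate > 0:
            hits = np.nonzero(rng.random(n) < sub_rate)[0]
            for i in hits:
                options = [b for b in alphabet if b != chars[i]]
                chars[i] = options[rng.integers(0, 3)]
        if indel_rate > 0:
            hits = sorted(np.nonzero(rng.random(n) < indel_rate)[0],
                          reverse=True)
            for i in hits:
                if rng.random() < 0.5:
                    del chars[i]
                else:
                    ins = "".join(alphabet[rng.integers(0, 4)]
                                  for _ in range(int(rng.integers(1, 4))))
                    chars.insert(i, ins)
        noisy.append(replace(read, sequence="".join(chars)))
    return FauxReadSet(noisy, read_set.read_len, read_set.step,
                       read_set.circular)


# ---------------------------------------------------------------------------
# truth alignments

@dataclass
class _Seg:
    """A read sub-window mapped to one reference interval."""

    r0: int
    r1: int
    chrom: str
    ref_start: int
    ref_end: int
    orient: str


def _window_segments(cmap: CoordinateMap, offset: int,
                     length: int) -> list[_Seg]:
    """Intersect a rearranged-sequence window with the map pieces.

    Returns segments in window order; neighbours that are reference-
    contiguous with equal orientation are merged — a read crossing such a
    boundary aligns straight through it.
    """
    total = cmap.length
    if cmap.circular:
        if length > total:
            raise SpecError("read longer than the circular sequence")
        spans = [(offset, min(offset + length, total))]
        if offset + length > total:
            spans.append((0, offset + length - total))
    else:
        if offset >= total:
            raise SpecError("read offset beyond the rearranged sequence")
        spans = [(offset, min(offset + length, total))]

    segs: list[_Seg] = []
    rpos = 0
    for span_start, span_end in spans:
        cum = 0
        for piece in cmap.pieces:
            p0, p1 = cum, cum + piece.length
            cum = p1
            s, e = max(span_start, p0), min(span_end, p1)
            if s >= e:
                continue
            if piece.orientation == "+":
                ref_s = piece.start + (s - p0)
                ref_e = piece.start + (e - p0)
            else:
                ref_s = piece.end - (e - p0)
                ref_e = piece.end - (s - p0)
            segs.append(_Seg(rpos, rpos + (e - s), piece.chrom,
                             ref_s, ref_e, piece.orientation))
            rpos += e - s

    merged: list[_Seg] = []
    for seg in segs:
        prev = merged[-1] if merged else None
        if (prev is not None and prev.chrom == seg.chrom
                and prev.orient == seg.orient and prev.r1 == seg.r0
                and ((seg.orient == "+" and prev.ref_end == seg.ref_start)
                     or (seg.orient == "-"
                         and prev.ref_start == seg.ref_end))):
            prev.r1 = seg.r1
            if seg.orient == "+":
                prev.ref_end = seg.ref_end
            else:
                prev.ref_start = seg.ref_start
        else:
            merged.append(seg)
    return merged


def _record_descriptor(read: FauxRead, seg: _Seg, window_seq: str,
                       primary: bool) -> dict:
    """SAM fields for one segment of one read.

    ``window_seq`` is the read in rearranged-sequence orientation.  A
    record's stored sequence is the window (or its reverse complement for
    a '-' piece); whether the *read as emitted* maps forward or reverse
    follows from combining piece orientation with emission orientation.
    """
    L = len(window_seq)
    is_rev = (seg.orient == "-") != (read.orientation == "-")
    if seg.orient == "+":
        lead, trail = seg.r0, L - seg.r1
        seq = window_seq
    else:
        lead, trail = L - seg.r1, seg.r0
        seq = revcomp(window_seq)
    cigar = []
    if lead:
        cigar.append((4, lead))
    cigar.append((0, seg.r1 - seg.r0))
    if trail:
        cigar.append((4, trail))
    return {
        "name": read.id,
        "chrom": seg.chrom,
        "pos": seg.ref_start,
        "is_rev": is_rev,
        "cigar": cigar,
        "seq": seq,
        "primary": primary,
        "strand": "-" if is_rev else "+",
    }


def _cigar_str(cigar: list[tuple[int, int]]) -> str:
    return "".join(f"{l}{'MIDNSHP=X'[op]}" for op, l in cigar)


def _sa_entry(d: dict) -> str:
    return (f"{d['chrom']},{d['pos'] + 1},{d['strand']},"
            f"{_cigar_str(d['cigar'])},{TRUTH_MAPQ},0;")


def _write_bam(descriptors: list[dict], out_path: str,
               reference_lengths: dict[str, int]) -> str:
    chroms = sorted(reference_lengths)
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": c, "LN": reference_lengths[c]} for c in chroms]}
    order = {c: i for i, c in enumerate(chroms)}
    descriptors.sort(key=lambda d: (order[d["chrom"]], d["pos"], d["name"]))
    with pysam.AlignmentFile(str(out_path), "wb", header=header) as bam:
        for d in descriptors:
            rec = pysam.AlignedSegment(bam.header)
            rec.query_name = d["name"]
            rec.flag = (16 if d["is_rev"] else 0) | \
                       (0 if d["primary"] else 2048)
            rec.reference_name = d["chrom"]
            rec.reference_start = d["pos"]
            rec.mapping_quality = TRUTH_MAPQ
            rec.cigartuples = d["cigar"]
            rec.query_sequence = d["seq"]
            tags = [("NM", 0)]
            if d.get("sa"):
                tags.append(("SA", d["sa"]))
            rec.set_tags(tags)
            bam.write(rec)
    pysam.index(str(out_path))
    return str(out_path)


def truth_alignments(read_sets: list[tuple[FauxReadSet, CoordinateMap]],
                     out_path: str,
                     reference_lengths: dict[str, int]) -> str:
    """Construct the exact split-read alignments for faux reads.

    Each read gets one primary record (its longest mapped segment) plus
    supplementary records for the rest, with mutually consistent SA tags
    (a supplementary's first SA entry is the primary).  The output BAM is
    coordinate-sorted and indexed.
    """
    descriptors: list[dict] = []
    for read_set, cmap in read_sets:
        for read in read_set.reads:
            window = (read.sequence if read.orientation == "+"
                      else revcomp(read.sequence))
            segs = _window_segments(cmap, read.offset, len(window))
            if not segs:
                raise SpecError(f"read {read.id} not derivable from map")
            longest = max(range(len(segs)),
                          key=lambda i: (segs[i].r1 - segs[i].r0, -i))
            recs = [_record_descriptor(read, seg, window, i == longest)
                    for i, seg in enumerate(segs)]
            if len(recs) > 1:
                prim = recs[longest]
                for i, rec in enumerate(recs):
                    # SA convention: on a supplementary the primary is
                    # listed first, then the rest in read order
                    others = [] if rec["primary"] else [prim]
                    others += [r for j, r in enumerate(recs)
                               if j != i and r is not prim]
                    rec["sa"] = "".join(_sa_entry(o) for o in others)
            descriptors.extend(recs)
    return _write_bam(descriptors, out_path, reference_lengths)


def gapped_truth_alignments(
        read_sets: list[tuple[FauxReadSet, CoordinateMap]],
        out_path: str, reference_lengths: dict[str, int]) -> str:
    """Write reads as single gapped alignments where the map allows it.

    Insertions and deletions relative to one chromosome are encoded in the
    CIGAR (I/D operations); reads whose geometry cannot be expressed as a
    gapped alignment (strand flips against the anchor, reference
    back-steps) fall back to the split-read representation.
    """
    descriptors: list[dict] = []
    for read_set, cmap in read_sets:
        for read in read_set.reads:
            window = (read.sequence if read.orientation == "+"
                      else revcomp(read.sequence))
            segs = _window_segments(cmap, read.offset, len(window))
            gapped = _gapped_descriptor(read, segs, window)
            if gapped is not None:
                descriptors.append(gapped)
                continue
            longest = max(range(len(segs)),
                          key=lambda i: (segs[i].r1 - segs[i].r0, -i))
            recs = [_record_descriptor(read, seg, window, i == longest)
                    for i, seg in enumerate(segs)]
            for i, rec in enumerate(recs):
                rec["sa"] = "".join(_sa_entry(o) for j, o in enumerate(recs)
                                    if j != i)
            descriptors.extend(recs)
    return _write_bam(descriptors, out_path, reference_lengths)


def _gapped_descriptor(read: FauxRead, segs: list[_Seg],
                       window: str) -> dict | None:
    anchors = [s for s in segs
               if s.chrom == segs[0].chrom and s.orient == "+"]
    if not anchors or segs[0] is not anchors[0] or segs[-1] is not anchors[-1]:
        return None
    L = len(window)
    first = anchors[0]
    cigar: list[tuple[int, int]] = []
    if first.r0:
        cigar.append((4, first.r0))
    cigar.append((0, first.r1 - first.r0))
    last_read_end, last_ref_end = first.r1, first.ref_end
    for seg in anchors[1:]:
        ins = seg.r0 - last_read_end
        dele = seg.ref_start - last_ref_end
        if dele < 0:
            return None
        if ins:
            cigar.append((1, ins))
        if dele:
            cigar.append((2, dele))
        cigar.append((0, seg.r1 - seg.r0))
        last_read_end, last_ref_end = seg.r1, seg.ref_end
    if L - last_read_end:
        cigar.append((4, L - last_read_end))
    return {
        "name": read.id,
        "chrom": first.chrom,
        "pos": first.ref_start,
        "is_rev": read.orientation == "-",
        "cigar": cigar,
        "seq": window,
        "primary": True,
        "strand": "+" if read.orientation == "+" else "-",
    }


def jittered_gapped_deletion_bam(
        out_path: str, reference: dict[str, str], chrom: str, start: int,
        end: int, n_reads: int, endpoint_jitter: int, seed: int,
        length_jitter: int = 0, flank: int = 12_000) -> str:
    """A gapped-alignment BAM for one deletion with per-read endpoint wobble.

    Noisy base calling shifts where each read places the deletion far more
    than it changes the reported length, so both endpoints move together
    by up to ``endpoint_jitter`` bases while the length wobbles by at most
    ``length_jitter``.  The read with index 0 reports the exact
    coordinates, so the cohort median recovers the truth for odd
    ``n_reads``.
    """
    rng = np.random.default_rng(seed)
    descriptors = []
    for i in range(n_reads):
        shift = 0 if i == 0 else int(rng.integers(-endpoint_jitter,
                                                  endpoint_jitter + 1))
        wobble = 0 if i == 0 or not length_jitter else \
            int(rng.integers(-length_jitter, length_jitter + 1))
        s, e = start + shift, end + shift + wobble
        a0 = s - flank
        b1 = e + flank
        seq = reference[chrom][a0:s] + reference[chrom][e:b1]
        cigar = [(0, s - a0), (2, e - s), (0, b1 - e)]
        # SEQ is stored in alignment orientation; the reverse flag only
        # records that odd reads were sequenced from the other strand
        descriptors.append({
            "name": f"gapped|r{i:05d}", "chrom": chrom, "pos": a0,
            "is_rev": i % 2 == 1, "cigar": cigar, "seq": seq,
            "primary": True, "strand": "+",
        })
    return _write_bam(descriptors,
                      out_path, {c: len(s) for c, s in reference.items()})


# ---------------------------------------------------------------------------
# the validation catalogue: 32 simple + 36 complex scenarios

def scenario_suite() -> list[RearrangementSpec]:
    """Deterministic catalogue of 68 rearrangements on the bundled reference.

    32 simple events (deletions, insertions, inversions, duplications,
    translocations and ring chromosomes, each kind in several size
    variants, translocations in balanced and unbalanced composites) and 36
    complex insertion-deletion events (origin on the same or the other
    chromosome, inverted or not, placed far from, near to, or within the
    copied sequence, with varying loss at the insertion site).
    """
    T = RearrangementType
    specs: list[RearrangementSpec] = []

    deletions = [("chrA", 200_000, 215_000), ("chrA", 140_000, 165_000),
                 ("chrB", 120_000, 160_000), ("chrA", 320_000, 380_000),
                 ("chrB", 200_000, 290_000), ("chrA", 150_000, 270_000)]
    for i, (c, s, e) in enumerate(deletions):
        specs.append(RearrangementSpec(
            f"del{i:02d}_{c}_{(e - s) // 1000}k", T.DELETION, c, s, e))

    inversions = [("chrA", 210_000, 228_000), ("chrB", 130_000, 160_000),
                  ("chrA", 260_000, 305_000), ("chrB", 180_000, 250_000),
                  ("chrA", 150_000, 250_000), ("chrA", 300_000, 440_000)]
    for i, (c, s, e) in enumerate(inversions):
        specs.append(RearrangementSpec(
            f"inv{i:02d}_{c}_{(e - s) // 1000}k", T.INVERSION, c, s, e))

    duplications = [("chrA", 220_000, 240_000), ("chrB", 140_000, 175_000),
                    ("chrA", 180_000, 230_000), ("chrB", 200_000, 280_000),
                    ("chrA", 350_000, 460_000)]
    for i, (c, s, e) in enumerate(duplications):
        specs.append(RearrangementSpec(
            f"dup{i:02d}_{c}_{(e - s) // 1000}k", T.TANDEM_DUPLICATION,
            c, s, e))

    insertions = [
        ("chrB", 120_000, 145_000, "chrA", 300_000, False),
        ("chrB", 200_000, 240_000, "chrA", 150_000, True),
        ("chrA", 100_000, 130_000, "chrA", 400_000, False),
        ("chrA", 350_000, 395_000, "chrA", 120_000, True),
        ("chrB", 80_000, 100_000, "chrA", 250_000, False),
        ("chrB", 300_000, 360_000, "chrA", 480_000, True),
        ("chrA", 200_000, 235_000, "chrB", 320_000, False),
        ("chrA", 440_000, 500_000, "chrB", 90_000, True),
    ]
    for i, (oc, x, y, c, p, inv) in enumerate(insertions):
        specs.append(RearrangementSpec(
            f"ins{i:02d}_{oc}to{c}_{(y - x) // 1000}k"
            f"{'_inv' if inv else ''}",
            T.INSERTION, c, origin_chrom=oc, origin_start=x, origin_end=y,
            insertion_point=p, inverted=inv))

    translocations = [
        (250_000, 200_000, "both"), (380_000, 120_000, "both"),
        (250_000, 200_000, "der1"), (150_000, 300_000, "der2"),
    ]
    for i, (pa, pb, der) in enumerate(translocations):
        balanced = der == "both"
        specs.append(RearrangementSpec(
            f"tra{i:02d}_{'bal' if balanced else 'unbal_' + der}",
            T.TRANSLOCATION_BALANCED if balanced
            else T.TRANSLOCATION_UNBALANCED,
            "chrA", pa, chrom2="chrB", pos2=pb, derivative=der))

    rings = [("chrA", 100_000, 400_000), ("chrB", 80_000, 380_000),
             ("chrA", 150_000, 550_000)]
    for i, (c, s, e) in enumerate(rings):
        specs.append(RearrangementSpec(
            f"ring{i:02d}_{c}_{(e - s) // 1000}k", T.RING_CHROMOSOME,
            c, s, e))

    assert len(specs) == 32, len(specs)

    # complex insertion-deletions, same chromosome: origin far from, near
    # to, or containing the insertion site
    sizes = [(20_000, 8_000), (35_000, 14_000), (50_000, 20_000)]
    for inv in (False, True):
        for prox in ("far", "near", "within"):
            for size, loss in sizes:
                if prox == "far":
                    x, p = 100_000, 350_000
                elif prox == "near":
                    x = 150_000
                    p = x + size + 4_000
                else:
                    x = 200_000
                    p = x + size // 2
                specs.append(RearrangementSpec(
                    f"cplx_same_{'inv' if inv else 'fwd'}_{prox}_"
                    f"{size // 1000}k",
                    T.COMPLEX_INSERTION_DELETION, "chrA",
                    origin_chrom="chrA", origin_start=x, origin_end=x + size,
                    insertion_point=p, loss_end=p + loss, inverted=inv))

    # complex insertion-deletions across chromosomes
    origin_sizes = [25_000, 40_000, 60_000]
    losses = [10_000, 18_000, 26_000]
    for inv in (False, True):
        for li, loss in enumerate(losses):
            for si, size in enumerate(origin_sizes):
                x = 100_000 + 40_000 * si
                p = 200_000 + 30_000 * li
                specs.append(RearrangementSpec(
                    f"cplx_cross_{'inv' if inv else 'fwd'}_l{loss // 1000}k_"
                    f"o{size // 1000}k",
                    T.COMPLEX_INSERTION_DELETION, "chrA",
                    origin_chrom="chrB", origin_start=x, origin_end=x + size,
                    insertion_point=p, loss_end=p + loss, inverted=inv))

    assert len(specs) == 68, len(specs)
    return specs


# ---------------------------------------------------------------------------
# scenario materialisation

def simulate_scenario(reference: dict[str, str], spec: RearrangementSpec,
                      bam_path: str,
                      read_len: int = DEFAULT_READ_LEN,
                      step: int = DEFAULT_STEP,
                      ) -> tuple[RearrangedGenome, dict]:
    """Apply a spec, tile reads over every rearranged contig, write the
    truth BAM, and return the genome together with its truth record."""
    genome = apply_rearrangement(reference, spec)
    read_sets = []
    for contig in genome.contigs:
        rs = make_faux_reads(contig.sequence, read_len, step,
                             circular=contig.cmap.circular,
                             id_prefix=contig.name)
        read_sets.append((rs, contig.cmap))
    lengths = {c: len(s) for c, s in reference.items()}
    truth_alignments(read_sets, bam_path, lengths)
    return genome, genome.truth_record()


def write_scenario_files(reference: dict[str, str], spec: RearrangementSpec,
                         outdir) -> dict:
    """Full per-scenario output: FASTAs, truth BAM, manifest and BEDPE."""
    from pathlib import Path

    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = apply_rearrangement(reference, spec)
    read_sets = []
    contig_records, read_records = [], []
    for contig in genome.contigs:
        rs = make_faux_reads(contig.sequence, circular=contig.cmap.circular,
                             id_prefix=contig.name)
        read_sets.append((rs, contig.cmap))
        contig_records.append(SeqRecord(Seq(contig.sequence),
                                        id=contig.name, description=""))
        read_records.extend(SeqRecord(Seq(r.sequence), id=r.id,
                                      description="") for r in rs.reads)
    SeqIO.write(contig_records, outdir / "rearranged.fasta", "fasta")
    SeqIO.write(read_records, outdir / "reads.fasta", "fasta")
    lengths = {c: len(s) for c, s in reference.items()}
    bam = truth_alignments(read_sets, str(outdir / "truth.bam"), lengths)
    truth = genome.truth_record()
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    _write_truth_bedpe(spec, outdir / "truth.bedpe")
    return {"bam": bam, "truth": truth, "dir": str(outdir)}


def _write_truth_bedpe(spec: RearrangementSpec, path) -> None:
    bps = sorted(spec.truth_breakpoints())
    lines = []
    if len(bps) == 2:
        (c1, p1), (c2, p2) = bps
        lines.append((c1, p1, c2, p2))
    else:
        site = [(c, p) for c, p in bps if c == spec.chrom
                and p in (spec.insertion_point, spec.loss_end)]
        origin = [(c, p) for c, p in bps if (c, p) not in site]
        for (c1, p1), (c2, p2) in zip(site, origin):
            lines.append((c1, p1, c2, p2))
    with open(path, "w") as fh:
        for i, (c1, p1, c2, p2) in enumerate(lines):
            fh.write(f"{c1}\t{p1}\t{p1 + 1}\t{c2}\t{p2}\t{p2 + 1}\t"
                     f"{spec.identifier}.{i}\t.\t+\t+\n")
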