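"""Junction extraction and breakpoint clustering.

Each pair of consecutive segments in a split read defines a *junction*: two
reference loci that the read joins but that are not adjacent in the
reference.  Junction ends from many reads are clustered per chromosome and
per side — a putative breakpoint is supported when two or more ends fall
within 250 nucleotides of each other.  Clusters that co-locate on a
chromosome are merged into *columns*, the visual unit of breakpoint
evidence: groups of split-read alignments that co-terminate at one
position.  Simple rearrangements show 2 columns (insertions 3), complex
insertion-deletion events 3 or 4.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple

from .alignment_io import RegionQuery, SplitRead
from .errors import ClassificationError

DEFAULT_WINDOW = 250        # nt within which junction ends co-cluster
DEFAULT_MIN_SUPPORT = 2     # ends required for a putative breakpoint
DEFAULT_HALF_WIDTH = 50_000  # secondary display window around a partner

LEFT = "left_of_break"    # position is a segment's ref_end: aligned
                          # sequence lies 5' (left) of the break
RIGHT = "right_of_break"  # position is a segment's ref_start


class JunctionEnd(NamedTuple):
    chrom: str
    pos: int
    side: str      # LEFT | RIGHT
    strand: str    # mapping strand of the contributing segment


@dataclass(frozen=True)
class Junction:
    """The join between two consecutive segments of one split read."""

    read_id: str
    a: JunctionEnd     # end contributed by the earlier segment in read order
    b: JunctionEnd     # end contributed by the later segment
    read_gap: int      # unaligned read bases between the segments, >= 0
    order_index: int   # position of this junction along the read

    @property
    def ends(self) -> tuple[JunctionEnd, JunctionEnd]:
        return self.a, self.b


def extract_junctions(split_read: SplitRead) -> list[Junction]:
    """One junction per consecutive segment pair, in read order.

    The earlier segment contributes the locus where its alignment stops
    reading 5'→3' along the read (ref_end on '+', ref_start on '-'); the
    later segment contributes the locus where its alignment resumes.
    """
    if len(split_read.segments) < 2:
        return []
    if not split_read.consistent:
        raise ClassificationError(
            f"read {split_read.read_id} failed the segment-overlap check "
            "and is excluded from junction extraction")
    junctions = []
    segs = split_read.segments
    for i in range(len(segs) - 1):
        prev, nxt = segs[i], segs[i + 1]
        if prev.strand == "+":
            a = JunctionEnd(prev.chrom, prev.ref_end, LEFT, "+")
        else:
            a = JunctionEnd(prev.chrom, prev.ref_start, RIGHT, "-")
        if nxt.strand == "+":
            b = JunctionEnd(nxt.chrom, nxt.ref_start, RIGHT, "+")
        else:
            b = JunctionEnd(nxt.chrom, nxt.ref_end, LEFT, "-")
        gap = max(0, nxt.read_start - prev.read_end)
        junctions.append(Junction(split_read.read_id, a, b, gap, i))
    return junctions


@dataclass
class BreakpointCluster:
    """A supported cluster of co-terminating junction ends on one side."""

    chrom: str
    position: int          # median of member positions, ties -> lower
    side: str
    support: int
    members: list[tuple[str, int, str]]             # (read_id, pos, strand)
    partners: list[JunctionEnd] = field(default_factory=list)

    @property
    def partner_summary(self) -> Counter:
        """Histogram of (partner chrom, partner position bin, strand)."""
        return Counter((p.chrom, p.pos // 1000, p.strand)
                       for p in self.partners)

    @property
    def read_ids(self) -> set[str]:
        return {m[0] for m in self.members}


def median_low(values: list[int]) -> int:
    """Median with ties broken toward the lower value."""
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def cluster_junctions(junctions: list[Junction],
                      window: int = DEFAULT_WINDOW,
                      min_support: int = DEFAULT_MIN_SUPPORT,
                      ) -> list[BreakpointCluster]:
    """Single-linkage clustering of junction ends per (chromosome, side).

    Sorted positions are merged while the gap between consecutive members is
    at most ``window``; clusters supported by fewer than ``min_support``
    ends are discarded.  Output order and content are independent of input
    order.
    """
    # (chrom, side) -> list of (pos, read_id, strand, partner end)
    groups: dict[tuple[str, str],
                 list[tuple[int, str, str, JunctionEnd]]] = {}
    for j in junctions:
        for end, partner in ((j.a, j.b), (j.b, j.a)):
            groups.setdefault((end.chrom, end.side), []).append(
                (end.pos, j.read_id, end.strand, partner))

    clusters: list[BreakpointCluster] = []
    for (chrom, side) in sorted(groups):
        entries = sorted(groups[(chrom, side)])
        run: list[tuple[int, str, str, JunctionEnd]] = []
        for entry in entries:
            if run and entry[0] - run[-1][0] > window:
                clusters.extend(
                    _finish_cluster(chrom, side, run, min_support))
                run = []
            run.append(entry)
        clusters.extend(_finish_cluster(chrom, side, run, min_support))
    clusters.sort(key=lambda c: (c.chrom, c.position, c.side))
    return clusters


def _finish_cluster(chrom: str, side: str,
                    run: list[tuple[int, str, str, JunctionEnd]],
                    min_support: int) -> list[BreakpointCluster]:
    if len(run) < min_support:
        return []
    positions = [e[0] for e in run]
    return [BreakpointCluster(
        chrom=chrom,
        position=median_low(positions),
        side=side,
        support=len(run),
        members=[(rid, pos, strand) for pos, rid, strand, _ in run],
        partners=[p for _, _, _, p in run],
    )]


@dataclass
class Column:
    """Breakpoint clusters that co-locate on a chromosome.

    Ends from both sides of a junction stack at the same reference
    coordinate (e.g. both flanks of an insertion point), so a column may
    merge a left-side and a right-side cluster at one locus.
    """

    chrom: str
    position: int
    clusters: list[BreakpointCluster]

    @property
    def support(self) -> int:
        return sum(c.support for c in self.clusters)

    @property
    def read_ids(self) -> set[str]:
        out: set[str] = set()
        for c in self.clusters:
            out |= c.read_ids
        return out

    @property
    def sides(self) -> set[str]:
        return {c.side for c in self.clusters}


@dataclass
class ColumnSet:
    columns: list[Column]
    pairing: list[tuple[int, int]]   # column index pairs joined by >=1 read

    @property
    def n_columns(self) -> int:
        return len(self.columns)


def build_columns(clusters: list[BreakpointCluster],
                  junctions: list[Junction],
                  window: int = DEFAULT_WINDOW) -> ColumnSet:
    """Merge co-located clusters into columns and link columns via reads.

    Two columns are paired when at least one junction has one end in each.
    The resulting column count and pairing topology feed classification.
    """
    columns: list[Column] = []
    for cl in sorted(clusters, key=lambda c: (c.chrom, c.position, c.side)):
        if (columns and columns[-1].chrom == cl.chrom
                and cl.position - columns[-1].position <= window):
            columns[-1].clusters.append(cl)
            columns[-1].position = median_low(
                [p for c in columns[-1].clusters for _, p, _ in c.members])
        else:
            columns.append(Column(cl.chrom, cl.position, [cl]))

    def locate(end: JunctionEnd) -> int | None:
        for i, col in enumerate(columns):
            if col.chrom == end.chrom and any(
                    c.side == end.side and abs(end.pos - c.position) <= window
                    for c in col.clusters):
                return i
        return None

    pairs: set[tuple[int, int]] = set()
    for j in junctions:
        ia, ib = locate(j.a), locate(j.b)
        if ia is not None and ib is not None and ia != ib:
            pairs.add((min(ia, ib), max(ia, ib)))
    return ColumnSet(columns, sorted(pairs))


def secondary_window(cluster: BreakpointCluster,
                     half_width: int = DEFAULT_HALF_WIDTH,
                     chrom_lengths: dict[str, int] | None = None,
                     ) -> RegionQuery:
    """Region around a cluster's modal partner locus, clipped to bounds."""
    if not cluster.partners:
        raise ClassificationError(
            f"cluster at {cluster.chrom}:{cluster.position} has no partner "
            "information")
    modal_bin, _ = cluster.partner_summary.most_common(1)[0]
    chrom, pos_bin, strand = modal_bin
    center = median_low([p.pos for p in cluster.partners
                         if (p.chrom, p.pos // 1000, p.strand) == modal_bin])
    start = max(0, center - half_width)
    end = center + half_width
    if chrom_lengths and chrom in chrom_lengths:
        end = min(end, chrom_lengths[chrom])
    return RegionQuery(chrom, start, end)
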