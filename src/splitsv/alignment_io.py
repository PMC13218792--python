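"""Read split-read alignments from indexed BAM files.

Long-read aligners report a read that spans a rearrangement junction as a
chain of local alignments: one *primary* record plus one or more
*supplementary* records, cross-referenced through the SAM ``SA`` tag.  This
module reconstructs that chain as a :class:`SplitRead` — an ordered list of
:class:`AlignmentSegment` placed on the read's own (forward-orientation)
coordinate axis, derived from each record's CIGAR clip structure.

Coordinates are 0-based half-open internally.  True secondary records
(flag 256) are ignored: the supported aligner invocation suppresses them,
and the partner alignments of a chimeric read are supplementary records.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pysam

from .errors import InputError, RegionError

logger = logging.getLogger(__name__)

BLOCK_LIMIT = 10_000_000  # largest region that may be screened in one query

# CIGAR operation codes (pysam numeric encoding)
_OP_CHARS = "MIDNSHP=X"
_CLIP_OPS = {4, 5}            # S, H: read bases outside this local alignment
_QUERY_OPS = {0, 1, 7, 8}     # M, I, =, X: consume aligned read bases
_REF_OPS = {0, 2, 3, 7, 8}    # M, D, N, =, X: consume reference bases

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def parse_cigar(cigar: str) -> list[tuple[int, int]]:
    """Parse a CIGAR string into pysam-style ``(op, length)`` tuples."""
    ops = [(_OP_CHARS.index(m.group(2)), int(m.group(1)))
           for m in _CIGAR_RE.finditer(cigar)]
    if not ops or "".join(f"{l}{_OP_CHARS[o]}" for o, l in ops) != cigar:
        raise ValueError(f"unparsable CIGAR: {cigar!r}")
    return ops


def cigar_to_string(cigartuples: list[tuple[int, int]]) -> str:
    return "".join(f"{l}{_OP_CHARS[o]}" for o, l in cigartuples)


def _clip_lengths(cigartuples: list[tuple[int, int]]) -> tuple[int, int]:
    lead = 0
    for op, length in cigartuples:
        if op not in _CLIP_OPS:
            break
        lead += length
    trail = 0
    for op, length in reversed(cigartuples):
        if op not in _CLIP_OPS:
            break
        trail += length
    return lead, trail


def read_coordinates(cigartuples: list[tuple[int, int]],
                     strand: str) -> tuple[int, int, int]:
    """Place one local alignment on the original read's forward axis.

    Returns ``(read_start, read_end, total_read_length)``.  Hard clips are
    treated identically to soft clips: either way the clipped bases exist on
    the read and shift the aligned window.  For a reverse-strand record the
    clips are reported in alignment orientation, so the leading clip counts
    from the read's 3' end and the window must be un-flipped.
    """
    lead, trail = _clip_lengths(cigartuples)
    qlen = sum(l for op, l in cigartuples if op in _QUERY_OPS)
    total = lead + qlen + trail
    read_start = lead if strand == "+" else trail
    return read_start, read_start + qlen, total


def reference_span(cigartuples: list[tuple[int, int]]) -> int:
    return sum(l for op, l in cigartuples if op in _REF_OPS)


@dataclass
class RegionQuery:
    """A bounded region of one chromosome (0-based half-open)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise RegionError(
                f"invalid region {self.chrom}:{self.start}-{self.end}")
        if self.end - self.start > BLOCK_LIMIT:
            raise RegionError(
                f"region {self.chrom}:{self.start}-{self.end} exceeds the "
                f"{BLOCK_LIMIT:,} bp block limit; screen in smaller blocks")

    @classmethod
    def from_string(cls, text: str) -> "RegionQuery":
        """Parse a 1-based inclusive ``chrom:start-end`` region string."""
        m = re.fullmatch(r"([^:]+):([\d,]+)-([\d,]+)", text.strip())
        if not m:
            raise RegionError(f"cannot parse region string {text!r}")
        start = int(m.group(2).replace(",", ""))
        end = int(m.group(3).replace(",", ""))
        return cls(m.group(1), start - 1, end)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start + 1}-{self.end}"


@dataclass
class AlignmentSegment:
    """One local alignment of part of a read.

    ``read_start``/``read_end`` are offsets on the original read in its
    forward orientation, so segments of one read can be ordered as they
    occur in the molecule regardless of mapping strand.
    """

    read_id: str
    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    read_start: int
    read_end: int
    mapq: int
    role: str                      # "primary" | "supplementary"
    cigar: list[tuple[int, int]] = field(default_factory=list)
    total_read_length: int = 0
    from_sa: bool = False          # synthesized from an SA entry

    def __post_init__(self) -> None:
        assert self.ref_start < self.ref_end, self
        assert self.read_start < self.read_end, self

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start

    @classmethod
    def from_pysam(cls, rec: pysam.AlignedSegment) -> "AlignmentSegment":
        strand = "-" if rec.is_reverse else "+"
        cig = list(rec.cigartuples or [])
        rs, re_, total = read_coordinates(cig, strand)
        return cls(
            read_id=rec.query_name,
            chrom=rec.reference_name,
            ref_start=rec.reference_start,
            ref_end=rec.reference_start + reference_span(cig),
            strand=strand,
            read_start=rs,
            read_end=re_,
            mapq=rec.mapping_quality,
            role="supplementary" if rec.is_supplementary else "primary",
            cigar=cig,
            total_read_length=total,
        )

    @classmethod
    def from_sa_entry(cls, read_id: str, entry: str) -> "AlignmentSegment":
        """Build a segment from one ``rname,pos,strand,CIGAR,mapQ,NM`` entry."""
        fields = entry.split(",")
        if len(fields) != 6:
            raise ValueError(f"malformed SA entry: {entry!r}")
        chrom, pos, strand, cigar, mapq, _nm = fields
        if strand not in "+-":
            raise ValueError(f"bad strand in SA entry: {entry!r}")
        cig = parse_cigar(cigar)
        rs, re_, total = read_coordinates(cig, strand)
        ref_start = int(pos) - 1
        return cls(
            read_id=read_id,
            chrom=chrom,
            ref_start=ref_start,
            ref_end=ref_start + reference_span(cig),
            strand=strand,
            read_start=rs,
            read_end=re_,
            mapq=int(mapq),
            role="supplementary",
            cigar=cig,
            total_read_length=total,
            from_sa=True,
        )


@dataclass
class SplitRead:
    """A read's ordered chain of alignment segments.

    ``consistent`` is False when consecutive segments overlap on the read by
    more than the configured tolerance; such reads are kept for display but
    excluded from junction extraction.
    """

    read_id: str
    segments: list[AlignmentSegment]
    total_read_length: int
    consistent: bool = True

    def __post_init__(self) -> None:
        assert self.segments, "a SplitRead needs at least one segment"

    @property
    def is_split(self) -> bool:
        return len(self.segments) > 1

    @property
    def primary(self) -> AlignmentSegment:
        for seg in self.segments:
            if seg.role == "primary":
                return seg
        return self.segments[0]


@dataclass
class GappedIndel:
    """An insertion or deletion encoded inside one alignment's CIGAR."""

    read_id: str
    kind: str          # "insertion" | "deletion"
    chrom: str
    ref_start: int
    ref_end: int       # == ref_start for insertions
    length: int
    read_start: int = 0  # forward-read coords of inserted bases
    read_end: int = 0

    def __post_init__(self) -> None:
        if self.kind == "deletion":
            assert self.length == self.ref_end - self.ref_start
        elif self.kind == "insertion":
            assert self.ref_start == self.ref_end
        else:
            raise ValueError(f"unknown indel kind {self.kind!r}")


def _open_bam(bam_path: str) -> pysam.AlignmentFile:
    try:
        bam = pysam.AlignmentFile(str(bam_path), "rb")
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot open BAM {bam_path}: {exc}") from exc
    if not bam.has_index():
        bam.close()
        raise InputError(f"BAM {bam_path} has no index (.bai); sort and "
                         "index it first")
    return bam


def read_alignments(bam_path: str, region: RegionQuery,
                    min_mapq: int = 0) -> list[AlignmentSegment]:
    """Extract every primary and supplementary record overlapping a region.

    True secondary records and unmapped records are excluded.  Raises
    :class:`RegionError` when the chromosome is absent from the header.
    """
    segments, _ = read_alignments_with_sa(bam_path, region, min_mapq)
    return segments


def read_alignments_with_sa(
        bam_path: str, region: RegionQuery, min_mapq: int = 0,
) -> tuple[list[AlignmentSegment], dict[str, list[str]]]:
    """Like :func:`read_alignments`, also collecting per-read SA tag values.

    SA tag values are kept in record-encounter order, primaries first, so a
    group whose primary lies outside the region can still recover it from
    the first entry of a supplementary's SA tag.
    """
    bam = _open_bam(bam_path)
    try:
        if region.chrom not in bam.references:
            raise RegionError(
                f"chromosome {region.chrom!r} not present in BAM header")
        segments: list[AlignmentSegment] = []
        sa_primary: dict[str, list[str]] = {}
        sa_supp: dict[str, list[str]] = {}
        for rec in bam.fetch(region.chrom, region.start, region.end):
            if rec.is_unmapped or rec.is_secondary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            if not rec.cigartuples:
                continue
            segments.append(AlignmentSegment.from_pysam(rec))
            if rec.has_tag("SA"):
                target = sa_supp if rec.is_supplementary else sa_primary
                target.setdefault(rec.query_name, []).append(rec.get_tag("SA"))
        sa_records = {}
        for rid in set(sa_primary) | set(sa_supp):
            sa_records[rid] = sa_primary.get(rid, []) + sa_supp.get(rid, [])
        return segments, sa_records
    finally:
        bam.close()


def link_split_reads(segments: list[AlignmentSegment],
                     sa_records: dict[str, list[str]] | None = None,
                     overlap_tol: int = 200,
                     min_mapq: int = 0) -> list[SplitRead]:
    """Group alignment segments by read and order them along the read.

    For reads whose SA tag references alignments outside the queried region,
    the missing segments are synthesized from the SA entries.  Unparsable SA
    entries are skipped with a logged warning.
    """
    sa_records = sa_records or {}
    by_read: dict[str, list[AlignmentSegment]] = {}
    for seg in segments:
        by_read.setdefault(seg.read_id, []).append(seg)

    reads: list[SplitRead] = []
    for read_id in sorted(by_read):
        group = by_read[read_id]
        seen = {(s.chrom, s.ref_start, s.strand) for s in group}
        first_sa_seg: AlignmentSegment | None = None
        for tag_value in sa_records.get(read_id, ()):
            for i, entry in enumerate(e for e in tag_value.split(";") if e):
                try:
                    synth = AlignmentSegment.from_sa_entry(read_id, entry)
                except ValueError as exc:
                    logger.warning("read %s: skipping SA entry: %s",
                                   read_id, exc)
                    continue
                if i == 0 and first_sa_seg is None:
                    first_sa_seg = synth
                key = (synth.chrom, synth.ref_start, synth.strand)
                if key in seen or synth.mapq < min_mapq:
                    continue
                seen.add(key)
                group.append(synth)
        if not any(s.role == "primary" for s in group):
            # the primary lies outside the query; by SA convention a
            # supplementary's first SA entry describes the primary
            for seg in group:
                if first_sa_seg is not None and (
                        seg.chrom, seg.ref_start, seg.strand) == (
                        first_sa_seg.chrom, first_sa_seg.ref_start,
                        first_sa_seg.strand):
                    seg.role = "primary"
                    break
            else:
                group[0].role = "primary"
        group.sort(key=lambda s: (s.read_start, s.read_end))
        total = max(s.total_read_length for s in group)
        consistent = all(
            group[i].read_end - group[i + 1].read_start <= overlap_tol
            for i in range(len(group) - 1))
        reads.append(SplitRead(read_id, group, total, consistent))
    return reads


def collect_split_reads(bam_path: str, region: RegionQuery,
                        min_mapq: int = 0,
                        overlap_tol: int = 200) -> list[SplitRead]:
    """One-stop extraction: fetch a region and reconstruct its split reads."""
    segments, sa_records = read_alignments_with_sa(bam_path, region, min_mapq)
    return link_split_reads(segments, sa_records, overlap_tol, min_mapq)


def scan_cigar_indels(segment: AlignmentSegment,
                      min_len: int = 10) -> list[GappedIndel]:
    """Report every I/D CIGAR operation strictly longer than ``min_len``.

    Reference coordinates locate the gap; for insertions the read
    coordinates of the inserted bases are given on the forward read.
    """
    out: list[GappedIndel] = []
    ref = segment.ref_start
    # read position in alignment orientation, including the leading clip
    lead, _ = _clip_lengths(segment.cigar)
    qpos = lead
    total = segment.total_read_length
    for op, length in segment.cigar:
        if op == 1 and length > min_len:  # I
            if segment.strand == "+":
                r0, r1 = qpos, qpos + length
            else:
                r0, r1 = total - (qpos + length), total - qpos
            out.append(GappedIndel(segment.read_id, "insertion",
                                   segment.chrom, ref, ref, length, r0, r1))
        elif op == 2 and length > min_len:  # D
            out.append(GappedIndel(segment.read_id, "deletion",
                                   segment.chrom, ref, ref + length, length))
        if op in _QUERY_OPS:
            qpos += length
        if op in _REF_OPS:
            ref += length
    return out
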