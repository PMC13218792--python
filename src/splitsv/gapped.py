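"""Indel calling from gapped alignments.

Some long-read aligners report a read spanning a rearrangement not as two
linked alignments but as one gapped alignment whose CIGAR string carries
the event as a long insertion or deletion operation.  Because a gapped
alignment is a series of collinear local alignments, this path can only
ever yield insertions and deletions — inversions and translocations
require split reads.

Events of the same kind are grouped across reads by single-linkage on
reference-span overlap (deletions) or on position proximity (insertions,
whose reference span is a point), then reduced to a median-consensus call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pysam

from .alignment_io import (AlignmentSegment, GappedIndel, RegionQuery,
                           _open_bam, scan_cigar_indels)
from .annotate import RearrangementCall, annotate_gapped
from .breakpoints import DEFAULT_WINDOW
from .errors import RegionError

logger = logging.getLogger(__name__)

DEFAULT_MIN_LEN = 10   # display/calling threshold on CIGAR indel length


@dataclass
class IndelGroup:
    kind: str
    chrom: str
    indels: list[GappedIndel] = field(default_factory=list)

    @property
    def read_ids(self) -> set[str]:
        return {i.read_id for i in self.indels}

    @property
    def support(self) -> int:
        return len(self.read_ids)

    @property
    def span(self) -> tuple[int, int]:
        return (min(i.ref_start for i in self.indels),
                max(i.ref_end for i in self.indels))


def collect_gapped(bam_path: str, region: RegionQuery,
                   min_len: int = DEFAULT_MIN_LEN, min_mapq: int = 0,
                   window: int = DEFAULT_WINDOW) -> list[IndelGroup]:
    """Scan primary alignments in a region for long CIGAR indels and group
    co-locating events of the same kind."""
    bam = _open_bam(bam_path)
    try:
        if region.chrom not in bam.references:
            raise RegionError(
                f"chromosome {region.chrom!r} not present in BAM header")
        indels: list[GappedIndel] = []
        for rec in bam.fetch(region.chrom, region.start, region.end):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq or not rec.cigartuples:
                continue
            seg = AlignmentSegment.from_pysam(rec)
            indels.extend(scan_cigar_indels(seg, min_len))
    finally:
        bam.close()

    groups: list[IndelGroup] = []
    for kind in ("deletion", "insertion"):
        events = sorted((i for i in indels if i.kind == kind),
                        key=lambda i: (i.ref_start, i.ref_end, i.read_id))
        current: IndelGroup | None = None
        reach = -1
        for ev in events:
            # deletions chain while their spans overlap; insertions (point
            # events) chain while within the clustering window
            chains = (ev.ref_start < reach if kind == "deletion"
                      else ev.ref_start - reach <= window)
            if current is not None and chains:
                current.indels.append(ev)
                reach = max(reach, ev.ref_end)
            else:
                current = IndelGroup(kind, ev.chrom, [ev])
                groups.append(current)
                reach = ev.ref_end
    logger.info("stage=gapped region=%s indels=%d groups=%d", region,
                len(indels), len(groups))
    return groups


def call_gapped(groups: list[IndelGroup],
                min_support: int = 2) -> list[RearrangementCall]:
    """Median-consensus calls per group; under-supported groups are kept
    but flagged low-confidence rather than dropped silently."""
    calls = []
    for group in groups:
        call = annotate_gapped(group.indels)
        if group.support < min_support:
            call.low_confidence = True
        calls.append(call)
    calls.sort(key=lambda c: (c.chrom_a, c.pos_a))
    return calls
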