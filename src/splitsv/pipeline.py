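"""End-to-end orchestration: detect -> classify -> annotate.

The original workflow is user-guided: breakpoint columns are found in a
queried region and the analyst selects which columns belong to one event.
This module reproduces that selection deterministically: columns joined by
shared split reads form connected components, each component is classified
from its signature, and two-component pairs are merged when their combined
evidence reads as a single insertion event (the two flank columns of a
complex insertion-deletion are otherwise disconnected and would each
masquerade as a simple rearrangement or a translocation).

The merge step assumes one event per analysed region — co-located
independent events can legitimately combine into an insertion-deletion
reading and need manual review, as multi-event loci always do.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .alignment_io import RegionQuery, SplitRead, link_split_reads, \
    read_alignments_with_sa
from .annotate import RearrangementCall, call_from_classification
from .breakpoints import (DEFAULT_MIN_SUPPORT, DEFAULT_WINDOW,
                          BreakpointCluster, ColumnSet, build_columns,
                          cluster_junctions, extract_junctions)
from .classify import (RearrangementType, classify_signature,
                       compute_signature)
from .errors import ClassificationError

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    reads: list[SplitRead]
    clusters: list[BreakpointCluster]
    columns: ColumnSet
    calls: list[RearrangementCall] = field(default_factory=list)


def collect_reads(bam_path: str, regions: list[RegionQuery],
                  min_mapq: int = 0,
                  overlap_tol: int = 200) -> list[SplitRead]:
    """Fetch and link split reads across regions, deduplicating reads that
    appear in more than one queried region."""
    seen: set[tuple] = set()
    segments = []
    sa_records: dict[str, list[str]] = {}
    for region in regions:
        segs, sa = read_alignments_with_sa(bam_path, region, min_mapq)
        for seg in segs:
            key = (seg.read_id, seg.chrom, seg.ref_start, seg.strand)
            if key not in seen:
                seen.add(key)
                segments.append(seg)
        for rid, tags in sa.items():
            existing = sa_records.setdefault(rid, [])
            for tag in tags:
                if tag not in existing:
                    existing.append(tag)
    return link_split_reads(segments, sa_records, overlap_tol, min_mapq)


def detect(bam_path: str, regions: list[RegionQuery],
           window: int = DEFAULT_WINDOW,
           min_support: int = DEFAULT_MIN_SUPPORT,
           min_mapq: int = 0, overlap_tol: int = 200) -> AnalysisResult:
    """Detection stage: split reads -> junctions -> clusters -> columns."""
    reads = collect_reads(bam_path, regions, min_mapq, overlap_tol)
    junctions = [j for r in reads if r.is_split and r.consistent
                 for j in extract_junctions(r)]
    clusters = cluster_junctions(junctions, window, min_support)
    columns = build_columns(clusters, junctions, window)
    logger.info("stage=detect regions=%d reads=%d junctions=%d clusters=%d "
                "columns=%d", len(regions), len(reads), len(junctions),
                len(clusters), len(columns.columns))
    return AnalysisResult(reads, clusters, columns)


def _components(columns: ColumnSet) -> list[list[int]]:
    parent = list(range(len(columns.columns)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in columns.pairing:
        parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(len(columns.columns)):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values())


def _reads_for_columns(result: AnalysisResult,
                       col_indices: list[int],
                       window: int) -> list[SplitRead]:
    wanted: set[str] = set()
    for i in col_indices:
        wanted |= result.columns.columns[i].read_ids
    return [r for r in result.reads if r.read_id in wanted]


def _classify_component(result: AnalysisResult, col_indices: list[int],
                        window: int):
    cols = [result.columns.columns[i] for i in col_indices]
    reads = _reads_for_columns(result, col_indices, window)
    sig = compute_signature(reads, cols, window)
    return sig, classify_signature(sig)


def analyze(bam_path: str, regions: list[RegionQuery],
            window: int = DEFAULT_WINDOW,
            min_support: int = DEFAULT_MIN_SUPPORT,
            min_mapq: int = 0, overlap_tol: int = 200) -> AnalysisResult:
    """Full pipeline over one or more (disjoint) regions."""
    result = detect(bam_path, regions, window, min_support, min_mapq,
                    overlap_tol)
    comps = _components(result.columns)

    classified: dict[int, tuple] = {}
    for ci, comp in enumerate(comps):
        try:
            classified[ci] = _classify_component(result, comp, window)
        except ClassificationError as exc:
            logger.info("stage=classify component=%d unusable: %s", ci, exc)

    # try to merge component pairs whose joint evidence reads as one
    # insertion event (flank columns of a complex rearrangement)
    merged_into: dict[int, int] = {}
    order = sorted(classified)
    for i_idx, ci in enumerate(order):
        if ci in merged_into:
            continue
        for cj in order[i_idx + 1:]:
            if cj in merged_into:
                continue
            both = sorted(comps[ci] + comps[cj])
            try:
                sig, cls = _classify_component(result, both, window)
            except ClassificationError:
                continue
            if cls.rtype in (RearrangementType.INSERTION,
                             RearrangementType.COMPLEX_INSERTION_DELETION):
                classified[ci] = (sig, cls)
                merged_into[cj] = ci
                logger.info("stage=classify merged components %d+%d -> %s",
                            ci, cj, cls.rtype)
                break

    calls = []
    for ci in sorted(classified):
        if ci in merged_into:
            continue
        sig, cls = classified[ci]
        call = call_from_classification(cls, sig)
        calls.append(call)
        logger.info("stage=annotate call=%s support=%d alternatives=%s",
                    call.hgvs_like, call.support,
                    ",".join(a.value for a in call.alternatives) or "-")
    calls.sort(key=lambda c: (c.chrom_a, c.pos_a, c.chrom_b, c.pos_b))
    result.calls = calls
    return result


def analyze_genome(bam_path: str, chrom_lengths: dict[str, int],
                   **kwargs) -> AnalysisResult:
    """Analyse whole chromosomes, split into block-limit-sized queries."""
    from .alignment_io import BLOCK_LIMIT
    regions = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        for start in range(0, length, BLOCK_LIMIT):
            regions.append(RegionQuery(chrom, start,
                                       min(length, start + BLOCK_LIMIT)))
    return analyze(bam_path, regions, **kwargs)
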