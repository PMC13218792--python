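"""Overlap of call breakpoints with gene / repeat interval tracks (BED)."""

from __future__ import annotations

import pandas as pd
from intervaltree import IntervalTree

from .annotate import RearrangementCall
from .errors import InputError


def load_bed(path: str) -> dict[str, IntervalTree]:
    """Load a BED 3+ file into per-chromosome interval trees.

    Intervals are 0-based half-open as in BED; the optional 4th column
    names the feature.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         dtype={0: str})
    except pd.errors.EmptyDataError:
        return {}
    if df.shape[1] < 3:
        raise InputError(f"{path}: BED needs at least 3 columns")
    trees: dict[str, IntervalTree] = {}
    for row in df.itertuples(index=False):
        chrom, start, end = str(row[0]), int(row[1]), int(row[2])
        if end <= start:
            continue
        name = str(row[3]) if df.shape[1] > 3 else f"{chrom}:{start}-{end}"
        trees.setdefault(chrom, IntervalTree()).addi(start, end, name)
    return trees


def annotate_overlaps(call: RearrangementCall,
                      trees: dict[str, IntervalTree]) -> list[dict]:
    """Features containing each breakpoint of a call.

    A breakpoint exactly on a half-open interval's end coordinate is
    outside the interval and is not reported.
    """
    out = []
    for chrom, pos in call.breakpoints0:
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in sorted(tree.at(pos)):
            out.append({"chrom": chrom, "position": pos + 1,
                        "feature": iv.data,
                        "feature_start": iv.begin + 1,
                        "feature_end": iv.end})
    return out
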