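"""Static two-panel depiction of split-read evidence.

The upper track shows primary alignments in the queried region, the lower
track the linked partner alignments within the secondary window of the
best-supported breakpoint.  Forward and reverse alignments and clipped
spans are visually distinct.  A text mode renders the same layout in
ASCII; the PNG mode needs matplotlib (optional extra)."""

from __future__ import annotations

from .alignment_io import RegionQuery, SplitRead
from .breakpoints import cluster_junctions, extract_junctions, \
    secondary_window
from .pipeline import collect_reads

_TEXT_WIDTH = 100


def _track_rows(reads: list[SplitRead], region: RegionQuery,
                role: str) -> list[tuple[str, list]]:
    rows = []
    for read in reads:
        segs = [s for s in read.segments
                if s.chrom == region.chrom and s.ref_start < region.end
                and s.ref_end > region.start
                and (role == "any" or s.role == role)]
        if segs:
            rows.append((read.read_id, segs))
    rows.sort(key=lambda r: min(s.ref_start for s in r[1]))
    return rows


def _ascii_track(rows, region: RegionQuery, width: int = _TEXT_WIDTH,
                 max_rows: int = 40) -> list[str]:
    span = region.end - region.start
    lines = []
    for read_id, segs in rows[:max_rows]:
        line = [" "] * width
        for seg in segs:
            a = max(0, (seg.ref_start - region.start) * width // span)
            b = min(width, max(a + 1,
                               (seg.ref_end - region.start) * width // span))
            mark = ">" if seg.strand == "+" else "<"
            for i in range(a, b):
                line[i] = mark
            # clipped read bases flanking the aligned span
            if seg.read_start > 0 and a > 0:
                line[a - 1] = "."
            if b < width:
                line[b] = "." if line[b] == " " else line[b]
        lines.append("".join(line).rstrip() + f"  {read_id}")
    if len(rows) > max_rows:
        lines.append(f"... and {len(rows) - max_rows} more reads")
    return lines


def render_text(bam_path: str, region: RegionQuery,
                half_width: int = 50_000, min_mapq: int = 0) -> str:
    """ASCII two-panel rendering; single panel when no split reads link
    out of the region."""
    reads = collect_reads(bam_path, [region], min_mapq)
    junctions = [j for r in reads if r.is_split and r.consistent
                 for j in extract_junctions(r)]
    clusters = cluster_junctions(junctions)
    out = [f"PRIMARY ALIGNMENTS  {region}",
           "=" * _TEXT_WIDTH]
    out += _ascii_track(_track_rows(reads, region, "primary"), region)
    best = max((c for c in clusters if c.partners), default=None,
               key=lambda c: c.support)
    if best is not None:
        partner_region = secondary_window(best, half_width)
        out += ["", f"LINKED SECONDARY ALIGNMENTS  {partner_region}  "
                    f"(partner of breakpoint {best.chrom}:"
                    f"{best.position + 1}, support {best.support})",
                "=" * _TEXT_WIDTH]
        out += _ascii_track(_track_rows(reads, partner_region, "any"),
                            partner_region)
    return "\n".join(out)


def render_png(bam_path: str, region: RegionQuery, out_path: str,
               half_width: int = 50_000, min_mapq: int = 0) -> str:
    """Two-panel PNG; requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    reads = collect_reads(bam_path, [region], min_mapq)
    junctions = [j for r in reads if r.is_split and r.consistent
                 for j in extract_junctions(r)]
    clusters = cluster_junctions(junctions)
    best = max((c for c in clusters if c.partners), default=None,
               key=lambda c: c.support)
    panels = [("primary alignments", region, "primary")]
    if best is not None:
        panels.append(("linked secondary alignments",
                       secondary_window(best, half_width), "any"))
    fig, axes = plt.subplots(len(panels), 1,
                             figsize=(10, 3 * len(panels)), squeeze=False)
    for ax, (title, reg, role) in zip(axes[:, 0], panels):
        rows = _track_rows(reads, reg, role)
        for y, (_, segs) in enumerate(rows):
            for seg in segs:
                color = "darkgreen" if seg.strand == "+" else "darkred"
                ax.plot([seg.ref_start, seg.ref_end], [y, y], lw=3,
                        color=color, solid_capstyle="butt")
        ax.set_xlim(reg.start, reg.end)
        ax.set_ylim(-1, max(10, len(rows)))
        ax.set_title(f"{title}  {reg}")
        ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path
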