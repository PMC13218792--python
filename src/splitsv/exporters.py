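"""Tabular and variant-format output: TSV, BEDPE, VCF (BND/symbolic), FASTA.

Reported coordinates are 1-based inclusive in TSV and VCF, 0-based
half-open in BEDPE, matching each format's convention.
"""

from __future__ import annotations

import pysam
import pandas as pd

from .annotate import RearrangementCall, RearrangementType
from .breakpoints import BreakpointCluster

_SYMBOLIC_ALT = {
    RearrangementType.DELETION: "DEL",
    RearrangementType.TANDEM_DUPLICATION: "DUP",
    RearrangementType.INVERSION: "INV",
    RearrangementType.INSERTION: "INS",
    RearrangementType.RING_CHROMOSOME: "DUP",
}


def calls_to_dataframe(calls: list[RearrangementCall]) -> pd.DataFrame:
    rows = []
    for call in calls:
        row = {
            "type": call.rtype.value,
            "alternatives": ",".join(a.value for a in call.alternatives),
            "chrom_a": call.chrom_a, "pos_a": call.pos_a,
            "chrom_b": call.chrom_b, "pos_b": call.pos_b,
            "support": call.support,
            "low_confidence": call.low_confidence,
            "annotation": call.hgvs_like,
        }
        if call.inserted_origin:
            oc, os_, oe, inv = call.inserted_origin
            row.update(origin=f"{oc}:{os_}-{oe}",
                       origin_inverted=inv)
        if call.loss_at_insertion:
            lc, ls, le = call.loss_at_insertion
            row.update(loss=f"{lc}:{ls}-{le}")
        rows.append(row)
    return pd.DataFrame(rows)


def write_calls_tsv(calls: list[RearrangementCall], path: str) -> None:
    calls_to_dataframe(calls).to_csv(path, sep="\t", index=False)


def write_clusters_tsv(clusters: list[BreakpointCluster],
                       path: str) -> None:
    rows = []
    for c in clusters:
        modal = c.partner_summary.most_common(1)
        partner = modal[0][0] if modal else (".", -1, ".")
        fwd = sum(1 for p in c.partners if p.strand == "+")
        rows.append({
            "chrom": c.chrom, "position": c.position + 1, "side": c.side,
            "support": c.support, "partner_chrom": partner[0],
            "partner_position": partner[1] * 1000 + 1,
            "partner_forward_fraction": round(fwd / len(c.partners), 3)
            if c.partners else float("nan"),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _breakpoint_pairs(call: RearrangementCall) -> list[tuple]:
    bps = call.breakpoints0
    if len(bps) <= 2:
        pair = bps if len(bps) == 2 else bps * 2
        return [tuple(pair)]
    site = [bp for bp in bps if bp[0] == call.chrom_a][:2]
    origin = [bp for bp in bps if bp not in site]
    return list(zip(site, origin)) or [tuple(bps[:2])]


def write_bedpe(calls: list[RearrangementCall], path: str) -> None:
    """One line per breakpoint pair (0-based half-open single-base spans)."""
    with open(path, "w") as fh:
        for i, call in enumerate(calls):
            for k, ((c1, p1), (c2, p2)) in enumerate(_breakpoint_pairs(call)):
                fh.write(f"{c1}\t{p1}\t{p1 + 1}\t{c2}\t{p2}\t{p2 + 1}\t"
                         f"{call.rtype.value}.{i}.{k}\t{call.support}\t"
                         "+\t+\n")


def write_vcf(calls: list[RearrangementCall], path: str,
              contig_lengths: dict[str, int]) -> None:
    """VCF 4.2: symbolic ALTs for intra-chromosomal simple events, BND
    mate pairs for translocations and complex events."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=splitsv",
    ]
    for chrom in sorted(contig_lengths):
        lines.append(f"##contig=<ID={chrom},length={contig_lengths[chrom]}>")
    lines += [
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description='
        '"Type of structural variant">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description='
        '"End position of the variant">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description='
        '"Length of the variant">',
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description='
        '"Supporting split reads">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description='
        '"ID of mate breakend">',
        '##INFO=<ID=EVENT,Number=1,Type=String,Description='
        '"Event annotation">',
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=DUP,Description="Duplication">',
        '##ALT=<ID=INV,Description="Inversion">',
        '##ALT=<ID=INS,Description="Insertion">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for i, call in enumerate(calls):
        if call.rtype == RearrangementType.UNCLASSIFIED:
            continue
        if (call.rtype in _SYMBOLIC_ALT
                and call.chrom_a == call.chrom_b
                and call.rtype != RearrangementType.INSERTION):
            svlen = call.pos_b - call.pos_a + 1
            if call.rtype == RearrangementType.DELETION:
                svlen = -svlen
            lines.append(
                f"{call.chrom_a}\t{call.pos_a}\tsv{i}\tN\t"
                f"<{_SYMBOLIC_ALT[call.rtype]}>\t.\tPASS\t"
                f"SVTYPE={_SYMBOLIC_ALT[call.rtype]};END={call.pos_b};"
                f"SVLEN={svlen};SUPPORT={call.support}")
        elif call.rtype == RearrangementType.INSERTION:
            length = call.ins_length
            if length is None and call.inserted_origin:
                length = call.inserted_origin[2] - call.inserted_origin[1] + 1
            lines.append(
                f"{call.chrom_a}\t{call.pos_a}\tsv{i}\tN\t<INS>\t.\tPASS\t"
                f"SVTYPE=INS;END={call.pos_a};SVLEN={length or 0};"
                f"SUPPORT={call.support}")
        else:
            alt_a = f"N[{call.chrom_b}:{call.pos_b}["
            alt_b = f"N]{call.chrom_a}:{call.pos_a}]"
            event = call.hgvs_like.replace(";", "|").replace("=", ":")
            lines.append(
                f"{call.chrom_a}\t{call.pos_a}\tsv{i}a\tN\t{alt_a}\t.\tPASS"
                f"\tSVTYPE=BND;MATEID=sv{i}b;SUPPORT={call.support};"
                f"EVENT={event}")
            lines.append(
                f"{call.chrom_b}\t{call.pos_b}\tsv{i}b\tN\t{alt_b}\t.\tPASS"
                f"\tSVTYPE=BND;MATEID=sv{i}a;SUPPORT={call.support};"
                f"EVENT={event}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_supporting_reads_fasta(bam_path: str, regions, read_ids,
                                 path: str) -> int:
    """Save the sequences of selected supporting reads (forward
    orientation, taken from their primary records)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    wanted = set(read_ids)
    records = {}
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        for region in regions:
            for rec in bam.fetch(region.chrom, region.start, region.end):
                if (rec.query_name not in wanted or rec.is_secondary
                        or rec.is_supplementary or not rec.query_sequence):
                    continue
                seq = rec.query_sequence
                if rec.is_reverse:
                    seq = str(Seq(seq).reverse_complement())
                records.setdefault(rec.query_name,
                                   SeqRecord(Seq(seq), id=rec.query_name,
                                             description=""))
    SeqIO.write(list(records.values()), path, "fasta")
    return len(records)
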