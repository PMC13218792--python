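"""Turn classified read sets into coordinate-annotated rearrangement calls.

Because base-calling errors shift individual alignments by a handful of
bases, every selected read is annotated independently and the per-read
coordinates are reduced to a single consensus with the per-coordinate
median (ties toward the lower coordinate).  Internally everything is
0-based half-open; reported coordinates are 1-based inclusive, so a
deletion of the reference span ``[s, e)`` is printed ``s+1 _ e del``.

Complex insertion-deletion events are reported descriptively rather than
in HGVS terms — the origin of the transposed sequence, whether it is
inverted, and the span lost at the insertion site — in a fixed
machine-parseable layout::

    INS(origin=chrA:x-y;inverted=yes|no);LOSS(chrB:p-q)
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .breakpoints import DEFAULT_WINDOW, median_low
from .classify import (Classification, JunctionClass, RearrangementType,
                       Signature, classify_signature, compute_signature)
from .errors import AnnotationError

logger = logging.getLogger(__name__)

SIMPLE_SPAN_TYPES = {
    RearrangementType.DELETION: "del",
    RearrangementType.TANDEM_DUPLICATION: "dup",
    RearrangementType.RING_CHROMOSOME: "ring",
    RearrangementType.INVERSION: "inv",
}


@dataclass
class RearrangementCall:
    """A classified, coordinate-annotated rearrangement."""

    rtype: RearrangementType
    alternatives: list[RearrangementType]
    chrom_a: str
    pos_a: int                    # 1-based in reports
    chrom_b: str
    pos_b: int
    support: int
    inserted_origin: tuple[str, int, int, bool] | None = None
    loss_at_insertion: tuple[str, int, int] | None = None
    ins_length: int | None = None
    per_read_annotations: list[tuple] = field(default_factory=list)
    breakpoints0: list[tuple[str, int]] = field(default_factory=list)
    low_confidence: bool = False
    details: dict = field(default_factory=dict)
    hgvs_like: str = ""

    def __post_init__(self) -> None:
        if not self.hgvs_like:
            self.hgvs_like = render_hgvs(self)


def consensus_coordinates(per_read: list[tuple]) -> tuple:
    """Per-coordinate median of equal-arity coordinate tuples.

    Elements may be integers or ``(chrom, pos)`` pairs; a slot mixing
    chromosomes is an error, since a median across chromosomes is
    meaningless.
    """
    if not per_read:
        raise AnnotationError("no coordinate tuples to aggregate")
    arity = len(per_read[0])
    if any(len(t) != arity for t in per_read):
        raise AnnotationError("coordinate tuples have mixed arity")
    out = []
    for slot in range(arity):
        values = [t[slot] for t in per_read]
        if isinstance(values[0], tuple):
            chroms = {v[0] for v in values}
            if len(chroms) > 1:
                raise AnnotationError(
                    f"coordinate slot {slot} mixes chromosomes: "
                    f"{sorted(chroms)}")
            out.append((values[0][0], median_low([v[1] for v in values])))
        else:
            out.append(median_low(list(values)))
    return tuple(out)


def _class_members(classes: list[JunctionClass], chrom: str, pos: int,
                   side: str) -> list[tuple[str, int]]:
    """Per-read positions of the class endpoint matching a partition role."""
    for c in classes:
        for which, end in zip("ab", c.endpoints):
            if (end.chrom, end.side) == (chrom, side) and end.pos == pos:
                idx = 1 if which == "a" else 2
                return [(m[0], m[idx]) for m in c.members]
    return []


def call_from_classification(cls: Classification, sig: Signature,
                             ) -> RearrangementCall:
    """Build a consensus-annotated call from a classified signature."""
    rtype = cls.rtype
    classes: list[JunctionClass] = cls.details.get("classes", [])
    reads = set().union(*(c.read_ids for c in classes)) if classes else set()

    if rtype == RearrangementType.UNCLASSIFIED:
        return RearrangementCall(
            rtype, [], "NA", 0, "NA", 0, support=len(reads),
            details=cls.details,
            hgvs_like=f"unclassified({cls.details.get('reason', '')})")

    if rtype in (RearrangementType.DELETION,
                 RearrangementType.TANDEM_DUPLICATION,
                 RearrangementType.INVERSION):
        per_read = [(m[0], m[1], m[2]) for c in classes for m in c.members]
        lo = median_low([t[1] for t in per_read])
        hi = median_low([t[2] for t in per_read])
        chrom = classes[0].a_chrom
        return RearrangementCall(
            rtype, cls.alternatives, chrom, lo + 1, chrom, hi,
            support=len(reads), per_read_annotations=per_read,
            breakpoints0=[(chrom, lo), (chrom, hi)], details=cls.details)

    if rtype in (RearrangementType.TRANSLOCATION_BALANCED,
                 RearrangementType.TRANSLOCATION_UNBALANCED):
        per_read = [(m[0], m[1], m[2]) for c in classes for m in c.members]
        pos_a = median_low([t[1] for t in per_read])
        pos_b = median_low([t[2] for t in per_read])
        chrom_a, chrom_b = classes[0].a_chrom, classes[0].b_chrom
        # reported positions are the last base 5' of each junction on the
        # + strand; with 0-based half-open internals that is the junction
        # offset itself
        return RearrangementCall(
            rtype, cls.alternatives, chrom_a, pos_a, chrom_b, pos_b,
            support=len(reads), per_read_annotations=per_read,
            breakpoints0=[(chrom_a, pos_a), (chrom_b, pos_b)],
            details=cls.details)

    if rtype in (RearrangementType.INSERTION,
                 RearrangementType.COMPLEX_INSERTION_DELETION):
        d = cls.details
        site_chrom = d["site_chrom"]
        origin_chrom = d["origin_chrom"]
        inverted = bool(d.get("inverted"))
        from .breakpoints import LEFT, RIGHT  # local to avoid cycle noise
        site_l = _class_members(classes, site_chrom, d["site_left"], LEFT)
        site_r = _class_members(classes, site_chrom, d["site_right"], RIGHT)
        org_s = _class_members(classes, origin_chrom, d["origin_start"],
                               RIGHT)
        org_e = _class_members(classes, origin_chrom, d["origin_end"], LEFT)
        p = median_low([v for _, v in site_l])
        q = median_low([v for _, v in site_r])
        x = median_low([v for _, v in org_s])
        y = median_low([v for _, v in org_e])
        origin = (origin_chrom, x + 1, y, inverted)
        if rtype == RearrangementType.INSERTION:
            return RearrangementCall(
                rtype, cls.alternatives, site_chrom, p, site_chrom, p + 1,
                support=len(reads), inserted_origin=origin,
                per_read_annotations=site_l + site_r,
                breakpoints0=[(site_chrom, p), (origin_chrom, x),
                              (origin_chrom, y)],
                details=cls.details)
        return RearrangementCall(
            rtype, cls.alternatives, site_chrom, p + 1, site_chrom, q,
            support=len(reads), inserted_origin=origin,
            loss_at_insertion=(site_chrom, p + 1, q),
            per_read_annotations=site_l + site_r,
            breakpoints0=[(site_chrom, p), (site_chrom, q),
                          (origin_chrom, x), (origin_chrom, y)],
            details=cls.details)

    raise AnnotationError(f"cannot annotate type {rtype}")  # pragma: no cover


def annotate_simple(reads, rtype, breakpoints=None,
                    window: int = DEFAULT_WINDOW) -> RearrangementCall:
    """Consensus annotation of reads classified as one simple type.

    The signature is recomputed from the selected reads and must agree
    with ``rtype`` (directly or as a reported alternative, e.g. forcing
    the ring-chromosome reading of a duplication-like signature);
    otherwise the offending reads are named.
    """
    expected = RearrangementType(rtype)
    sig = compute_signature(reads, breakpoints, window)
    cls = classify_signature(sig)
    if cls.rtype != expected and expected not in cls.alternatives:
        main = max(sig.classes, key=lambda c: c.support)
        offending = sorted(set().union(
            *(c.read_ids for c in sig.classes if c is not main)) or
            main.read_ids)
        raise AnnotationError(
            f"selected reads classify as {cls.rtype}, not {expected}; "
            f"inconsistent reads: {', '.join(offending)}")
    call = call_from_classification(cls, sig)
    if expected != cls.rtype and expected in cls.alternatives:
        # the user asserts the alternative reading (e.g. ring chromosome)
        call.alternatives = [cls.rtype] + [a for a in call.alternatives
                                           if a != expected]
        call.rtype = expected
        call.hgvs_like = render_hgvs(call)
    return call


def annotate_complex(reads_a, reads_b=None,
                     window: int = DEFAULT_WINDOW) -> RearrangementCall:
    """Descriptive annotation from two selected columns of split reads.

    Both flank columns of the insertion site must be provided: a single
    column of a complex event can masquerade as a simple rearrangement
    (e.g. a translocation when two chromosomes are involved).
    """
    if not reads_b:
        raise AnnotationError(
            "complex annotation needs the split reads of both flank "
            "columns; a single column risks misannotation — re-examine "
            "the selection")
    by_id = {r.read_id: r for r in list(reads_a) + list(reads_b)}
    sig = compute_signature(list(by_id.values()), None, window)
    cls = classify_signature(sig)
    if cls.rtype not in (RearrangementType.COMPLEX_INSERTION_DELETION,
                         RearrangementType.INSERTION):
        raise AnnotationError(
            "selected columns are not joined to a common inserted-origin "
            "locus (classified as "
            f"{cls.rtype}); it may be necessary to re-examine the reads "
            "selected")
    return call_from_classification(cls, sig)


def annotate_gapped(indels) -> RearrangementCall:
    """Median-aggregated call from CIGAR-encoded indels across reads."""
    indels = list(indels)
    if not indels:
        raise AnnotationError("no gapped indels to annotate")
    kinds = {i.kind for i in indels}
    if len(kinds) > 1:
        raise AnnotationError(
            f"cannot aggregate mixed indel kinds: {sorted(kinds)}")
    chroms = {i.chrom for i in indels}
    if len(chroms) > 1:
        raise AnnotationError(
            f"cannot aggregate indels across chromosomes: {sorted(chroms)}")
    kind = kinds.pop()
    chrom = chroms.pop()
    read_ids = {i.read_id for i in indels}
    low_confidence = len(read_ids) < 2
    if low_confidence:
        logger.warning("gapped %s at %s supported by a single read", kind,
                       chrom)
    if kind == "deletion":
        s = median_low([i.ref_start for i in indels])
        e = median_low([i.ref_end for i in indels])
        return RearrangementCall(
            RearrangementType.DELETION, [], chrom, s + 1, chrom, e,
            support=len(read_ids), low_confidence=low_confidence,
            per_read_annotations=[(i.read_id, i.ref_start, i.ref_end)
                                  for i in indels],
            breakpoints0=[(chrom, s), (chrom, e)])
    pos = median_low([i.ref_start for i in indels])
    length = median_low([i.length for i in indels])
    return RearrangementCall(
        RearrangementType.INSERTION, [], chrom, pos, chrom, pos + 1,
        support=len(read_ids), ins_length=length,
        low_confidence=low_confidence,
        per_read_annotations=[(i.read_id, i.ref_start, i.length)
                              for i in indels],
        breakpoints0=[(chrom, pos)])


def render_hgvs(call: RearrangementCall) -> str:
    """Deterministic, regenerable annotation string for a call."""
    t = call.rtype
    if t in SIMPLE_SPAN_TYPES and t != RearrangementType.RING_CHROMOSOME:
        suffix = SIMPLE_SPAN_TYPES[t]
        return f"{call.chrom_a}:{call.pos_a}_{call.pos_b}{suffix}"
    if t == RearrangementType.RING_CHROMOSOME:
        return f"ring({call.chrom_a}:{call.pos_a}_{call.pos_b})"
    if t in (RearrangementType.TRANSLOCATION_BALANCED,
             RearrangementType.TRANSLOCATION_UNBALANCED):
        return (f"t({call.chrom_a};{call.chrom_b})"
                f"(g.{call.pos_a};g.{call.pos_b})")
    if t == RearrangementType.INSERTION:
        if call.inserted_origin is not None:
            oc, os_, oe, inv = call.inserted_origin
            tag = "inv" if inv else ""
            return (f"{call.chrom_a}:{call.pos_a}_{call.pos_b}"
                    f"ins[{oc}:{os_}_{oe}{tag}]")
        return (f"{call.chrom_a}:{call.pos_a}_{call.pos_b}"
                f"ins{call.ins_length}")
    if t == RearrangementType.COMPLEX_INSERTION_DELETION:
        oc, os_, oe, inv = call.inserted_origin
        lc, ls, le = call.loss_at_insertion
        return (f"INS(origin={oc}:{os_}-{oe};"
                f"inverted={'yes' if inv else 'no'});"
                f"LOSS({lc}:{ls}-{le})")
    return f"unclassified({call.details.get('reason', 'unknown pattern')})"


_SPAN_RE = re.compile(r"^([^:]+):(\d+)_(\d+)(del|dup|inv)$")
_TRANS_RE = re.compile(r"^t\(([^;]+);([^)]+)\)\(g\.(\d+);g\.(\d+)\)$")
_RING_RE = re.compile(r"^ring\(([^:]+):(\d+)_(\d+)\)$")


def parse_hgvs(text: str) -> RearrangementCall:
    """Rebuild a simple call from its rendered annotation string."""
    m = _SPAN_RE.match(text)
    if m:
        rtype = {"del": RearrangementType.DELETION,
                 "dup": RearrangementType.TANDEM_DUPLICATION,
                 "inv": RearrangementType.INVERSION}[m.group(4)]
        return RearrangementCall(rtype, [], m.group(1), int(m.group(2)),
                                 m.group(1), int(m.group(3)), support=0)
    m = _RING_RE.match(text)
    if m:
        return RearrangementCall(
            RearrangementType.RING_CHROMOSOME, [], m.group(1),
            int(m.group(2)), m.group(1), int(m.group(3)), support=0)
    m = _TRANS_RE.match(text)
    if m:
        return RearrangementCall(
            RearrangementType.TRANSLOCATION_BALANCED, [], m.group(1),
            int(m.group(3)), m.group(2), int(m.group(4)), support=0)
    raise AnnotationError(f"cannot parse annotation {text!r}")
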