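"""Signature canonicalisation, the decision table, and provable ambiguity."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splitsv.alignment_io import RegionQuery
from splitsv.breakpoints import LEFT, RIGHT
from splitsv.classify import (JunctionClass, RearrangementType, Signature,
                              assess_complexity, classify_signature,
                              compute_signature)
from splitsv.errors import ClassificationError
from splitsv.pipeline import detect
from splitsv.simulate import (RearrangementSpec, simulate_scenario)

from .conftest import make_split_read

T = RearrangementType


def _deletion_reads(n=6, chrom="chrZ", s=100_000, e=140_000):
    return [make_split_read(f"r{i}", [
        (chrom, s - 5000, s, "+", 0, 5000),
        (chrom, e, e + 5000, "+", 5000, 10_000),
    ]) for i in range(n)]


def _duplication_reads(n=6, chrom="chrZ", s=100_000, e=140_000):
    # the end of the span joined back to its start
    return [make_split_read(f"r{i}", [
        (chrom, e - 5000, e, "+", 0, 5000),
        (chrom, s, s + 5000, "+", 5000, 10_000),
    ]) for i in range(n)]


def _inversion_reads(n=6, chrom="chrZ", s=100_000, e=140_000):
    reads = []
    for i in range(n):
        if i % 2 == 0:  # left breakpoint: '+' into '-'
            reads.append(make_split_read(f"r{i}", [
                (chrom, s - 5000, s, "+", 0, 5000),
                (chrom, e - 5000, e, "-", 5000, 10_000),
            ]))
        else:  # right breakpoint: '-' into '+'
            reads.append(make_split_read(f"r{i}", [
                (chrom, s, s + 5000, "-", 0, 5000),
                (chrom, e, e + 5000, "+", 5000, 10_000),
            ]))
    return reads


def _translocation_reads(n=6, reciprocal=True):
    reads = []
    for i in range(n):
        if reciprocal and i % 2:
            reads.append(make_split_read(f"r{i}", [
                ("chrB", 195_000, 200_000, "+", 0, 5000),
                ("chrA", 250_000, 255_000, "+", 5000, 10_000),
            ]))
        else:
            reads.append(make_split_read(f"r{i}", [
                ("chrA", 245_000, 250_000, "+", 0, 5000),
                ("chrB", 200_000, 205_000, "+", 5000, 10_000),
            ]))
    return reads


class TestDecisionTable:
    def test_deletion_pattern(self):
        sig = compute_signature(_deletion_reads())
        cls = classify_signature(sig)
        assert cls.rtype == T.DELETION and cls.alternatives == []

    def test_reversed_order_pattern_is_ambiguous(self):
        """End-joined-to-start is a tandem duplication with the ring
        chromosome as an unresolvable alternative."""
        cls = classify_signature(compute_signature(_duplication_reads()))
        assert cls.rtype == T.TANDEM_DUPLICATION
        assert cls.alternatives == [T.RING_CHROMOSOME]

    def test_mirrored_opposite_strand_pattern_is_inversion(self):
        cls = classify_signature(compute_signature(_inversion_reads()))
        assert cls.rtype == T.INVERSION and cls.alternatives == []

    def test_reciprocal_cross_chromosome_is_balanced_translocation(self):
        cls = classify_signature(
            compute_signature(_translocation_reads(reciprocal=True)))
        assert cls.rtype == T.TRANSLOCATION_BALANCED

    def test_one_sided_cross_chromosome_is_unbalanced(self):
        cls = classify_signature(
            compute_signature(_translocation_reads(reciprocal=False)))
        assert cls.rtype == T.TRANSLOCATION_UNBALANCED

    def test_shared_site_with_distal_origin_is_insertion(self):
        reads = []
        for i in range(6):
            if i % 2 == 0:
                reads.append(make_split_read(f"r{i}", [
                    ("chrA", 295_000, 300_000, "+", 0, 5000),
                    ("chrB", 120_000, 125_000, "+", 5000, 10_000),
                ]))
            else:
                reads.append(make_split_read(f"r{i}", [
                    ("chrB", 140_000, 145_000, "+", 0, 5000),
                    ("chrA", 300_000, 305_000, "+", 5000, 10_000),
                ]))
        cls = classify_signature(compute_signature(reads))
        assert cls.rtype == T.INSERTION
        assert cls.details["origin_chrom"] == "chrB"
        assert (cls.details["origin_start"],
                cls.details["origin_end"]) == (120_000, 145_000)

    def test_distinct_site_flanks_mean_loss(self):
        reads = []
        for i in range(6):
            if i % 2 == 0:
                reads.append(make_split_read(f"r{i}", [
                    ("chrA", 195_000, 200_000, "+", 0, 5000),
                    ("chrB", 100_000, 105_000, "+", 5000, 10_000),
                ]))
            else:
                reads.append(make_split_read(f"r{i}", [
                    ("chrB", 120_000, 125_000, "+", 0, 5000),
                    ("chrA", 210_000, 215_000, "+", 5000, 10_000),
                ]))
        cls = classify_signature(compute_signature(reads))
        assert cls.rtype == T.COMPLEX_INSERTION_DELETION
        assert cls.alternatives == []
        assert cls.details["loss"] == 10_000

    def test_inverted_same_chrom_loss_flags_offset_inversion(self):
        reads = []
        for i in range(6):
            if i % 2 == 0:
                reads.append(make_split_read(f"r{i}", [
                    ("chrA", 295_000, 300_000, "+", 0, 5000),
                    ("chrA", 135_000, 140_000, "-", 5000, 10_000),
                ]))
            else:
                reads.append(make_split_read(f"r{i}", [
                    ("chrA", 100_000, 105_000, "-", 0, 5000),
                    ("chrA", 310_000, 315_000, "+", 5000, 10_000),
                ]))
        cls = classify_signature(compute_signature(reads))
        assert cls.rtype == T.COMPLEX_INSERTION_DELETION
        assert T.INVERSION in cls.alternatives

    def test_no_qualifying_reads_is_an_error(self):
        with pytest.raises(ClassificationError):
            compute_signature(_deletion_reads(), [("chrQ", 5)])


class TestDeterminism:
    def test_signature_is_order_independent(self):
        reads = _inversion_reads(10)
        ref = compute_signature(reads).canonical_json()
        rng = random.Random(5)
        for _ in range(3):
            rng.shuffle(reads)
            assert compute_signature(reads).canonical_json() == ref

    def test_emitted_orientation_does_not_change_signature(self,
                                                           scenario_bam):
        """Alternating faux-read orientations collapse to one canonical
        junction class."""
        bam, *_ = scenario_bam("del00_chrA_15k")
        result = detect(bam, [RegionQuery("chrA", 0, 600_000)])
        reads = [r for r in result.reads if r.is_split]
        sig = compute_signature(reads, result.columns.columns)
        assert len(sig.classes) == 1
        assert sig.classes[0].support == len(reads)


class TestAmbiguousPairs:
    def test_ring_and_duplication_signatures_identical(self, reference,
                                                       ref_lengths,
                                                       tmp_path):
        """A ring chromosome and a tandem duplication built on identical
        breakpoints produce byte-identical canonical signatures."""
        s, e = 150_000, 450_000
        sigs = []
        for kind in (T.TANDEM_DUPLICATION, T.RING_CHROMOSOME):
            spec = RearrangementSpec(f"amb_{kind.value}", kind, "chrA",
                                     s, e)
            bam = str(tmp_path / f"{kind.value}.bam")
            simulate_scenario(reference, spec, bam)
            result = detect(bam, [RegionQuery("chrA", 0, 600_000)])
            reads = [r for r in result.reads if r.is_split]
            sigs.append(compute_signature(reads, result.columns.columns)
                        .canonical_json())
        assert sigs[0] == sigs[1]

    def test_offset_inversion_pair_signatures_identical(self, reference,
                                                        tmp_path):
        """An inverted insertion-deletion and the offset inversion that
        re-describes the same molecule serialise identically."""
        spec_insdel = RearrangementSpec(
            "amb_insdel", T.COMPLEX_INSERTION_DELETION, "chrA",
            origin_chrom="chrA", origin_start=100_000, origin_end=140_000,
            insertion_point=300_000, loss_end=310_000, inverted=True)
        # the same rearranged molecule, described as an inversion of
        # [100k, 300k) displaced with loss of [140k, 310k)
        spec_offset = RearrangementSpec(
            "amb_offset", T.COMPLEX_INSERTION_DELETION, "chrA",
            origin_chrom="chrA", origin_start=100_000, origin_end=300_000,
            insertion_point=140_000, loss_end=310_000, inverted=True)
        sigs = []
        for spec in (spec_insdel, spec_offset):
            bam = str(tmp_path / f"{spec.identifier}.bam")
            genome, _ = simulate_scenario(reference, spec, bam)
            result = detect(bam, [RegionQuery("chrA", 0, 600_000)])
            reads = [r for r in result.reads if r.is_split]
            sigs.append(compute_signature(reads, result.columns.columns)
                        .canonical_json())
        assert sigs[0] == sigs[1]


@st.composite
def junction_classes(draw):
    chroms = ["chr1", "chr2"]
    n = draw(st.integers(1, 4))
    out = []
    for i in range(n):
        a_chrom = draw(st.sampled_from(chroms))
        b_chrom = draw(st.sampled_from(chroms))
        a_pos = draw(st.integers(0, 1_000_000))
        b_pos = draw(st.integers(0, 1_000_000))
        if (b_chrom, b_pos) < (a_chrom, a_pos):
            a_chrom, b_chrom = b_chrom, a_chrom
            a_pos, b_pos = b_pos, a_pos
        a_side = draw(st.sampled_from([LEFT, RIGHT]))
        b_side = draw(st.sampled_from([LEFT, RIGHT]))
        strands_equal = draw(st.booleans())
        support = draw(st.integers(1, 10))
        members = [(f"c{i}r{k}", a_pos, b_pos) for k in range(support)]
        out.append(JunctionClass(a_chrom, a_side, b_chrom, b_side,
                                 strands_equal, "+",
                                 "+" if strands_equal else "-", members))
    return out


class TestTotality:
    @given(classes=junction_classes())
    @settings(max_examples=200, deadline=None)
    def test_classify_never_raises(self, classes):
        """Every syntactically valid signature gets a call, never an
        exception; unknown patterns come back unclassified."""
        sig = Signature(classes, n_columns=len(classes) + 1,
                        n_reads=sum(c.support for c in classes),
                        n_excluded=0)
        cls = classify_signature(sig)
        assert isinstance(cls.rtype, RearrangementType)
        assert isinstance(cls.alternatives, list)


class TestComplexityAssessment:
    def test_two_columns_simple(self, scenario_bam):
        bam, *_ = scenario_bam("del00_chrA_15k")
        result = detect(bam, [RegionQuery("chrA", 0, 600_000)])
        assert assess_complexity(result.columns).label == "simple"

    def test_insertion_topology_three_columns_simple(self, scenario_bam):
        bam, *_ = scenario_bam("ins00_chrBtochrA_25k")
        result = detect(bam, [RegionQuery("chrA", 0, 600_000),
                              RegionQuery("chrB", 0, 450_000)])
        assert result.columns.n_columns == 3
        assert assess_complexity(result.columns).label == "simple"

    def test_four_columns_complex(self, scenario_bam):
        bam, *_ = scenario_bam("cplx_cross_fwd_l10k_o25k")
        result = detect(bam, [RegionQuery("chrA", 0, 600_000),
                              RegionQuery("chrB", 0, 450_000)])
        assert result.columns.n_columns == 4
        assert assess_complexity(result.columns).label == "complex"

    def test_more_than_four_columns_warns(self):
        from splitsv.breakpoints import Column, ColumnSet
        cols = ColumnSet([Column("chrA", i * 50_000, []) for i in range(6)],
                         [])
        assessment = assess_complexity(cols)
        assert assessment.label == "complex"
        assert "manual review" in assessment.warning
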