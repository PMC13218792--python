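"""Simulator invariants: maps, faux reads, truth alignments, the catalogue."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from splitsv.classify import RearrangementType
from splitsv.errors import SpecError
from splitsv.simulate import (RearrangementSpec, add_read_noise,
                              apply_rearrangement, make_faux_reads, revcomp,
                              scenario_suite, synthetic_reference,
                              truth_alignments)

T = RearrangementType


class TestApplyRearrangement:
    def test_deletion_length_and_pieces(self, reference):
        spec = RearrangementSpec("d", T.DELETION, "chrA", 100_000, 130_000)
        genome = apply_rearrangement(reference, spec)
        (contig,) = genome.contigs
        assert len(contig.sequence) == len(reference["chrA"]) - 30_000
        assert len(contig.cmap.pieces) == 2

    def test_inversion_middle_piece_reverse(self, reference):
        spec = RearrangementSpec("i", T.INVERSION, "chrA", 100_000, 130_000)
        (contig,) = apply_rearrangement(reference, spec).contigs
        orients = [p.orientation for p in contig.cmap.pieces]
        assert orients == ["+", "-", "+"]
        assert contig.sequence[100_000:130_000] == \
               revcomp(reference["chrA"][100_000:130_000])

    def test_ring_is_single_circular_piece(self, reference):
        spec = RearrangementSpec("r", T.RING_CHROMOSOME, "chrA", 100_000,
                                 400_000)
        (contig,) = apply_rearrangement(reference, spec).contigs
        assert contig.cmap.circular
        assert len(contig.cmap.pieces) == 1
        assert len(contig.sequence) == 300_000

    def test_length_bookkeeping_over_whole_suite(self, reference, suite):
        """Rearranged length equals the sum of map piece lengths for
        every catalogue scenario."""
        for spec in suite:
            for contig in apply_rearrangement(reference, spec).contigs:
                assert len(contig.sequence) == contig.cmap.length

    def test_out_of_bounds_span_rejected(self, reference):
        spec = RearrangementSpec("bad", T.DELETION, "chrA", 100, 10**9)
        with pytest.raises(SpecError, match="bounds"):
            apply_rearrangement(reference, spec)


class TestMakeFauxReads:
    def test_offsets_and_alternating_orientations(self):
        seq = "ACGT" * 3000  # 12 kb
        rs = make_faux_reads(seq)
        assert [r.offset for r in rs.reads] == list(range(0, 12_000, 1000))
        assert [r.orientation for r in rs.reads[:4]] == ["+", "-", "+", "-"]
        assert len(rs.reads[0].sequence) == 10_000
        # tail windows are emitted truncated so coverage reaches the end
        assert len(rs.reads[-1].sequence) == 1000

    def test_short_sequence_single_truncated_forward_read(self):
        rs = make_faux_reads("ACGTT" * 1000)  # 5 kb
        assert len(rs.reads) == 5
        assert rs.reads[0].orientation == "+"
        assert len(rs.reads[0].sequence) == 5000

    def test_every_read_is_substring_or_revcomp(self, reference):
        """Property over a composite rearrangement: each faux read is an
        exact substring (or reverse complement) of the input sequence."""
        spec = RearrangementSpec(
            "p", T.COMPLEX_INSERTION_DELETION, "chrA",
            origin_chrom="chrB", origin_start=50_000, origin_end=90_000,
            insertion_point=200_000, loss_end=215_000, inverted=True)
        (contig,) = apply_rearrangement(reference, spec).contigs
        rs = make_faux_reads(contig.sequence)
        rng = np.random.default_rng(23)
        for i in rng.integers(0, len(rs.reads), 40):
            read = rs.reads[i]
            window = contig.sequence[read.offset:read.offset + 10_000]
            expected = window if read.orientation == "+" else revcomp(window)
            assert read.sequence == expected

    def test_ring_reads_wrap_the_junction(self, reference):
        spec = RearrangementSpec("r", T.RING_CHROMOSOME, "chrA", 100_000,
                                 400_000)
        (contig,) = apply_rearrangement(reference, spec).contigs
        rs = make_faux_reads(contig.sequence, circular=True)
        wrapping = [r for r in rs.reads
                    if r.offset + 10_000 > len(contig.sequence)]
        assert wrapping
        read = wrapping[0]
        doubled = contig.sequence + contig.sequence
        window = doubled[read.offset:read.offset + 10_000]
        assert len(read.sequence) == 10_000
        assert read.sequence in (window, revcomp(window))


class TestTruthAlignments:
    def _bam_records(self, reference, spec, tmp_path, circular=False):
        (contig,) = apply_rearrangement(reference, spec).contigs
        rs = make_faux_reads(contig.sequence,
                             circular=contig.cmap.circular)
        path = str(tmp_path / "t.bam")
        truth_alignments([(rs, contig.cmap)], path,
                         {c: len(s) for c, s in reference.items()})
        with pysam.AlignmentFile(path) as bam:
            return list(bam.fetch())

    def test_interior_read_is_single_primary_without_sa(self, reference,
                                                        tmp_path):
        spec = RearrangementSpec("d", T.DELETION, "chrA", 200_000, 230_000)
        records = self._bam_records(reference, spec, tmp_path)
        by_read: dict[str, list] = {}
        for rec in records:
            by_read.setdefault(rec.query_name, []).append(rec)
        interior = [recs for recs in by_read.values() if len(recs) == 1]
        assert interior
        for (rec,) in interior:
            assert not rec.is_supplementary and not rec.has_tag("SA")

    def test_junction_read_reference_gap_equals_deleted_length(
            self, reference, tmp_path):
        spec = RearrangementSpec("d", T.DELETION, "chrA", 200_000, 230_000)
        records = self._bam_records(reference, spec, tmp_path)
        by_read: dict[str, list] = {}
        for rec in records:
            by_read.setdefault(rec.query_name, []).append(rec)
        split = {k: v for k, v in by_read.items() if len(v) == 2}
        assert split
        for recs in split.values():
            recs.sort(key=lambda r: r.reference_start)
            assert recs[0].reference_end == 200_000
            assert recs[1].reference_start == 230_000

    def test_exactly_one_primary_per_read_and_sa_consistency(
            self, reference, tmp_path):
        spec = RearrangementSpec(
            "x", T.INSERTION, "chrA", origin_chrom="chrB",
            origin_start=50_000, origin_end=80_000, insertion_point=200_000)
        records = self._bam_records(reference, spec, tmp_path)
        by_read: dict[str, list] = {}
        for rec in records:
            by_read.setdefault(rec.query_name, []).append(rec)
        for recs in by_read.values():
            primaries = [r for r in recs if not r.is_supplementary]
            assert len(primaries) == 1
            if len(recs) == 1:
                continue
            described = {(r.reference_name, r.reference_start + 1,
                          "-" if r.is_reverse else "+") for r in recs}
            for rec in recs:
                own = (rec.reference_name, rec.reference_start + 1,
                       "-" if rec.is_reverse else "+")
                listed = set()
                for entry in rec.get_tag("SA").rstrip(";").split(";"):
                    chrom, pos, strand, *_ = entry.split(",")
                    listed.add((chrom, int(pos), strand))
                assert listed == described - {own}

    def test_supplementary_sa_lists_primary_first(self, reference,
                                                  tmp_path):
        spec = RearrangementSpec("d", T.DELETION, "chrA", 200_000, 230_000)
        records = self._bam_records(reference, spec, tmp_path)
        primaries = {r.query_name: r for r in records
                     if not r.is_supplementary}
        checked = 0
        for rec in records:
            if not rec.is_supplementary:
                continue
            first = rec.get_tag("SA").split(";")[0].split(",")
            prim = primaries[rec.query_name]
            assert (first[0], int(first[1]) - 1) == \
                   (prim.reference_name, prim.reference_start)
            checked += 1
        assert checked


class TestScenarioSuite:
    def test_catalogue_size_is_68(self, suite):
        assert len(suite) == 68
        simple = [s for s in suite
                  if s.kind != T.COMPLEX_INSERTION_DELETION]
        assert len(simple) == 32

    def test_exactly_two_ambiguity_classes(self, suite):
        classes = {s.ambiguity_class for s in suite if s.ambiguity_class}
        assert classes == {
            "ring_vs_tandem_duplication",
            "offset_inversion_vs_inverted_insertion_deletion"}

    def test_every_simple_kind_has_size_variants(self, suite):
        spans: dict[T, set[int]] = {}
        for s in suite:
            if s.kind in (T.DELETION, T.INVERSION, T.TANDEM_DUPLICATION,
                          T.RING_CHROMOSOME):
                spans.setdefault(s.kind, set()).add(s.end - s.start)
            elif s.kind == T.INSERTION:
                spans.setdefault(s.kind, set()).add(
                    s.origin_end - s.origin_start)
        for kind, sizes in spans.items():
            assert len(sizes) >= 2, kind
        translocs = {(s.start, s.pos2) for s in suite
                     if s.kind in (T.TRANSLOCATION_BALANCED,
                                   T.TRANSLOCATION_UNBALANCED)}
        assert len(translocs) >= 2

    def test_reference_is_deterministic(self):
        a = synthetic_reference()
        b = synthetic_reference()
        assert a == b


class TestReadNoise:
    def _reads(self):
        rng = np.random.default_rng(2)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 40_000))
        return make_faux_reads(seq)

    def test_zero_rates_identity(self):
        rs = self._reads()
        noisy = add_read_noise(rs, 0.0, 0.0, seed=5)
        assert [r.sequence for r in noisy.reads] == \
               [r.sequence for r in rs.reads]

    def test_fixed_seed_reproducible(self):
        rs = self._reads()
        a = add_read_noise(rs, 0.05, 0.01, seed=9)
        b = add_read_noise(rs, 0.05, 0.01, seed=9)
        assert [r.sequence for r in a.reads] == \
               [r.sequence for r in b.reads]

    def test_substitution_count_is_binomial(self):
        """With indels off, per-read mismatches are Binomial(L, rate):
        check the pooled count within 3 sigma of expectation."""
        rs = self._reads()
        rate = 0.05
        noisy = add_read_noise(rs, rate, 0.0, seed=13)
        mismatches = total = 0
        for before, after in zip(rs.reads, noisy.reads):
            assert len(before.sequence) == len(after.sequence)
            mismatches += sum(a != b for a, b in zip(before.sequence,
                                                     after.sequence))
            total += len(before.sequence)
        mean = total * rate
        sigma = (total * rate * (1 - rate)) ** 0.5
        assert abs(mismatches - mean) <= 3 * sigma
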