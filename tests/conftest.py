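"""Shared fixtures: the bundled reference and cached scenario truth BAMs."""

from __future__ import annotations

import pytest

from splitsv.alignment_io import AlignmentSegment, SplitRead
from splitsv.simulate import (RearrangementSpec, scenario_suite,
                              simulate_scenario, synthetic_reference)


@pytest.fixture(scope="session")
def reference() -> dict[str, str]:
    return synthetic_reference()


@pytest.fixture(scope="session")
def ref_lengths(reference) -> dict[str, int]:
    return {c: len(s) for c, s in reference.items()}


@pytest.fixture(scope="session")
def suite() -> list[RearrangementSpec]:
    return scenario_suite()


@pytest.fixture(scope="session")
def scenario_bam(reference, suite, tmp_path_factory):
    """Factory: truth BAM for a catalogue scenario, cached per session."""
    root = tmp_path_factory.mktemp("scenarios")
    cache: dict[str, tuple] = {}

    def build(identifier: str):
        if identifier not in cache:
            spec = next(s for s in suite if s.identifier == identifier)
            path = str(root / f"{identifier}.bam")
            genome, truth = simulate_scenario(reference, spec, path)
            cache[identifier] = (path, spec, genome, truth)
        return cache[identifier]

    return build


def make_segment(read_id: str, chrom: str, ref_start: int, ref_end: int,
                 strand: str, read_start: int, read_end: int,
                 role: str = "supplementary",
                 mapq: int = 60) -> AlignmentSegment:
    return AlignmentSegment(read_id=read_id, chrom=chrom,
                            ref_start=ref_start, ref_end=ref_end,
                            strand=strand, read_start=read_start,
                            read_end=read_end, mapq=mapq, role=role)


def make_split_read(read_id: str, segs: list[tuple],
                    total: int | None = None) -> SplitRead:
    """Build a SplitRead from (chrom, ref_start, ref_end, strand,
    read_start, read_end) tuples; the first segment is the primary."""
    segments = [make_segment(read_id, *spec,
                             role="primary" if i == 0 else "supplementary")
                for i, spec in enumerate(segs)]
    segments.sort(key=lambda s: s.read_start)
    total = total or max(s.read_end for s in segments)
    return SplitRead(read_id, segments, total)
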