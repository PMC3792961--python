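"""Shared fixtures: small genomes, mutated-genome pairs, and read sets are
generated programmatically at test time (no stored data files)."""

from __future__ import annotations

import pytest

from readpolish.fixtures import ReadErrorProfile, generate_reads, random_genome
from readpolish.formats_io import AlignedRead, ReferenceGenome
from readpolish.simulate import SimulateParams, mutate_genome


@pytest.fixture(scope="session")
def genome_20kb() -> ReferenceGenome:
    return random_genome(20_000, seed=11)


@pytest.fixture(scope="session")
def mutated_pair(genome_20kb):
    """(mutated genome, truth table) with 40 SNPs and 12 indels."""
    params = SimulateParams(snp_count=40, indel_count=12, seed=7)
    return mutate_genome(genome_20kb, params)


@pytest.fixture(scope="session")
def clean_reads(genome_20kb):
    """Error-free 30x paired-end reads aligned to their own genome."""
    reads, errors = generate_reads(
        genome_20kb, depth=30, read_len=75, insert_mean=250, insert_sd=20, seed=5
    )
    assert not errors
    return reads


def make_read(
    chrom: str = "c1",
    pos: int = 1,
    cigar=((4, "M"),),
    seq: str = "ACGT",
    quals=None,
    name: str = "r1",
    **kw,
) -> AlignedRead:
    """Small helper for hand-built reads."""
    if quals is None:
        quals = [30] * len(seq)
    return AlignedRead(
        name=name,
        chrom=chrom,
        pos=pos,
        strand="+",
        cigar=[tuple(c) for c in cigar],
        seq=seq,
        quals=list(quals),
        **kw,
    )
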