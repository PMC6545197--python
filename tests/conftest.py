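"""Shared fixtures: toy circular genomes with a permuted intron-exon layout,
and one session-scoped synthetic study reused across classifier tests."""

from __future__ import annotations

import numpy as np
import pytest

from mitosplice import (
    CircularGenome,
    IntronModel,
    SimConfig,
    build_junction_library,
    enumerate_junctions,
    generate_genome,
    generate_transcript_pool,
)


def make_toy(rng: np.random.Generator, L: int = 40, e2_end: int = 6,
             linker_end: int = 10, e1_start: int = 10, five_ss: int = 15):
    """Toy circular genome: exon2 [0, e2_end), linker, exon1 [e1_start, five_ss),
    giant intron [five_ss, 0) wrapping through the origin."""
    seq = "".join(rng.choice(list("ACGT"), size=L))
    genome = CircularGenome("toy", seq)
    intron = IntronModel(
        id="toy-intron", five_ss=five_ss, three_ss=0,
        exon1_start=e1_start, exon2_end=e2_end, host_gene="toy",
    )
    return genome, intron


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy(rng):
    """The 40-nt toy layout: exon2 [0,6), linker [6,10), exon1 [10,15), intron [15,0)."""
    return make_toy(rng)


@pytest.fixture
def toy_big(rng):
    """A toy large enough for k=6 junction flanks: exon2 [0,10), linker [10,16),
    exon1 [16,28), intron [28,0) on a 70-nt circle."""
    return make_toy(rng, L=70, e2_end=10, linker_end=16, e1_start=16, five_ss=28)


@pytest.fixture(scope="session")
def study():
    """One synthetic study (default conditions, modest read count) shared by
    classifier/stats tests."""
    cfg = SimConfig(seed=11, n_reads=8000)
    genome, features, introns = generate_genome(cfg)
    pool = generate_transcript_pool(genome, features, introns, cfg)
    juncs = []
    for intron in introns:
        offs = cfg.circle_offsets if intron.id == "COI-884" else ()
        juncs.extend(enumerate_junctions(genome, intron, k=25, circle_offsets=offs))
    lib = build_junction_library(juncs, k=25)
    return {"cfg": cfg, "genome": genome, "features": features,
            "introns": introns, "pool": pool, "junctions": juncs, "lib": lib}
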