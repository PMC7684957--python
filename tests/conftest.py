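"""Shared fixtures: synthetic genomes reused across test modules.

Simulation fixtures are session-scoped because genome generation and
profiling dominate the suite's run time; every test that consumes them is
read-only.
"""

import pytest

import kmerspectra as ks


@pytest.fixture(scope="session")
def uniform_profiles():
    """Three fixed-seed uniform i.i.d. 1 Mb genomes profiled at k=6."""
    profiles = []
    for seed in (1, 2, 3):
        seq = ks.generate(ks.build_spec(1.0, 1.0, 0.5, 1_000_000, seed=seed))
        profiles.append(ks.profile_genome(seq, 6, genome_id=f"uniform_{seed}"))
    return profiles


@pytest.fixture(scope="session")
def graded_group():
    """20 Markov genomes, cg_factor graded 1.0 -> 0.2, L = 1 Mb, k = 6.

    Profiled with the three-way scheme so the CG2 class is defined.
    Returns (profiles, specs with the true factors).
    """
    seqs, specs = ks.make_group(20, cg_range=(1.0, 0.2), length=1_000_000, seed=42)
    profiles = [
        ks.profile_genome(s, 6, scheme="three-way", genome_id=f"graded_{i:02d}")
        for i, s in enumerate(seqs)
    ]
    return profiles, specs


@pytest.fixture(scope="session")
def anti_group():
    """20 genomes with cg and ta depletion anti-correlated (L = 500 kb)."""
    seqs, specs = ks.make_group(
        20, cg_range=(1.0, 0.2), ta_range=(1.0, 0.2),
        anti_correlate=True, length=500_000, seed=43,
    )
    profiles = [
        ks.profile_genome(s, 6, genome_id=f"anti_{i:02d}")
        for i, s in enumerate(seqs)
    ]
    return profiles, specs


@pytest.fixture(scope="session")
def depleted_genome():
    """One strongly CG-depleted genome (cg_factor 0.2, 300 kb) and its profile."""
    seq = ks.generate(ks.build_spec(0.2, 1.0, 0.5, 300_000, seed=7))
    return seq, ks.profile_genome(seq, 6, genome_id="depleted")
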