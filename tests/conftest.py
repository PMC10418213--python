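"""Shared fixtures: small architectures and cohorts reused across test modules.

Everything is seeded; session-scoped fixtures hold the expensive objects
(simulated cohorts) so the suite stays fast.
"""

import numpy as np
import pytest

from admixherit import (
    SimulationConfig,
    assign_effect_magnitudes,
    draw_source_frequencies,
    permute_signs_select,
    simulate_admixture,
)


@pytest.fixture(scope="session")
def freqs_small():
    """60 Balding-Nichols loci at F=0.2."""
    return draw_source_frequencies(60, F=0.2, seed=11)


@pytest.fixture(scope="session")
def arch_divergent(freqs_small):
    beta = assign_effect_magnitudes(freqs_small)
    return permute_signs_select(
        freqs_small, beta, n_perm=100, criterion="max_ld_contribution", seed=12
    )


@pytest.fixture(scope="session")
def arch_stabilizing(freqs_small):
    beta = assign_effect_magnitudes(freqs_small)
    return permute_signs_select(
        freqs_small, beta, n_perm=100, criterion="min_ld_contribution", seed=12
    )


@pytest.fixture(scope="session")
def arch_neutral(freqs_small):
    beta = assign_effect_magnitudes(freqs_small)
    return permute_signs_select(
        freqs_small, beta, n_perm=1, criterion="random", seed=13
    )


@pytest.fixture(scope="session")
def hi_trajectory(arch_divergent):
    """HI trajectory, n=600, generations 0..3, random mating."""
    cfg = SimulationConfig(model="hi", p=0.5, P=0.0, T=3, n=600, seed=21)
    return simulate_admixture(cfg, arch_divergent, keep="all")


@pytest.fixture(scope="session")
def hi_cohort(hi_trajectory):
    """The generation-2 cohort of the shared HI trajectory."""
    return hi_trajectory[2]


@pytest.fixture(scope="session")
def unstructured_genotypes():
    """Single-population genotypes: n=500, m=80, no ancestry structure."""
    rng = np.random.default_rng(31)
    f = rng.uniform(0.1, 0.9, size=80)
    X = rng.binomial(2, f, size=(500, 80)).astype(np.int8)
    return X
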