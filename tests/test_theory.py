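"""Closed-form decomposition, estimand table, ancestry recursions, oracles."""

import numpy as np
import pytest

from admixherit import (
    ArchitectureSpec,
    SimulationConfig,
    SourceFrequencies,
    ancestry_moments,
    assign_effect_magnitudes,
    draw_source_frequencies,
    estimand_table,
    expected_ancestry_moments,
    he_estimand_decomposition,
    local_ancestry_components,
    permute_signs_select,
    simulate_admixture,
    variance_components,
)
from admixherit.theory import simulated_variance_oracle


class TestVarianceComponents:
    def test_no_ancestry_variance_kills_theta_terms(self, arch_divergent):
        d = variance_components(arch_divergent, 0.5, 0.0)
        assert d.term_1_3 == 0.0 and d.term_1_4 == 0.0
        assert d.term_1_1 > 0 and d.term_1_2 > 0

    def test_identical_populations_leave_only_genic_term(self):
        fr = SourceFrequencies(
            f0=np.array([0.4, 0.6]), fA=np.array([0.4, 0.6]),
            fB=np.array([0.4, 0.6]), F=0.2,
        )
        arch = ArchitectureSpec(freqs=fr, beta=np.array([1.0, -1.0]))
        d = variance_components(arch, 0.3, 0.1)
        assert d.term_1_2 == d.term_1_3 == d.term_1_4 == 0.0
        expected = 2 * (0.4 * 0.6 + 0.6 * 0.4)
        assert d.term_1_1 == pytest.approx(expected)

    def test_theta_terms_scale_linearly_in_vtheta(self, arch_divergent):
        d1 = variance_components(arch_divergent, 0.5, 0.05)
        d2 = variance_components(arch_divergent, 0.5, 0.10)
        assert d2.term_1_3 == pytest.approx(2 * d1.term_1_3, rel=1e-12)
        assert d2.term_1_4 == pytest.approx(2 * d1.term_1_4, rel=1e-12)

    def test_impossible_moments_rejected(self, arch_divergent):
        with pytest.raises(ValueError):
            variance_components(arch_divergent, 0.5, 0.3)
        with pytest.raises(ValueError):
            variance_components(arch_divergent, 1.5, 0.1)

    def test_totals_and_dict(self, arch_divergent):
        d = variance_components(arch_divergent, 0.4, 0.1)
        assert d.total == pytest.approx(
            d.term_1_1 + d.term_1_2 + d.term_1_3 + d.term_1_4
        )
        assert d.genic == pytest.approx(d.total - d.term_1_4)
        keys = d.as_dict()
        for k in ("term_1_1", "term_1_2", "term_1_3", "term_1_4"):
            assert k in keys


class TestLocalAncestryComponents:
    def test_matches_theta_dependent_genotype_terms(self, arch_divergent):
        dg = variance_components(arch_divergent, 0.5, 0.12)
        dl = local_ancestry_components(arch_divergent, 0.5, 0.12)
        assert dl.term_1_1 == 0.0
        assert dl.total == pytest.approx(
            dg.term_1_2 + dg.term_1_3 + dg.term_1_4, rel=1e-12
        )

    def test_identical_populations_explain_nothing(self):
        fr = SourceFrequencies(
            f0=np.array([0.5]), fA=np.array([0.5]), fB=np.array([0.5]), F=0.2
        )
        arch = ArchitectureSpec(freqs=fr, beta=np.array([2.0]))
        assert local_ancestry_components(arch, 0.5, 0.2).total == 0.0


class TestEstimandTable:
    def test_cells(self, arch_divergent):
        d = variance_components(arch_divergent, 0.5, 0.12)
        tab = estimand_table(d)
        assert tab[("standard", False)] == pytest.approx(d.term_1_1 + d.term_1_2)
        assert tab[("variance", False)] == pytest.approx(
            d.term_1_1 + d.term_1_2 + d.term_1_3
        )
        assert tab[("ld", False)] == pytest.approx(d.total)
        adj = d.term_1_1 + d.term_1_2 - d.term_1_3
        for scaling in ("standard", "variance", "ld"):
            assert tab[(scaling, True)] == pytest.approx(adj)

    def test_no_structure_collapses_the_table(self, arch_divergent):
        tab = estimand_table(variance_components(arch_divergent, 0.5, 0.0))
        vals = list(tab.values())
        # without V(theta) the only spread left is the directional-LD term,
        # which is zero, so unadjusted cells coincide
        assert vals[0] == pytest.approx(tab[("variance", False)])

    def test_divergent_ordering(self, arch_divergent):
        tab = estimand_table(variance_components(arch_divergent, 0.5, 0.12))
        assert tab[("ld", False)] > tab[("variance", False)] > tab[("standard", False)]
        assert tab[("standard", True)] < tab[("standard", False)]

    def test_local_ancestry_flavor_rejected(self, arch_divergent):
        with pytest.raises(ValueError):
            estimand_table(local_ancestry_components(arch_divergent, 0.5, 0.1))


class TestAncestryMomentRecursions:
    def test_hi_initial_and_halving(self):
        E, V = expected_ancestry_moments("hi", p=0.5, P=0.0, T=4)
        assert np.all(E == 0.5)
        assert V[0] == pytest.approx(0.25)
        np.testing.assert_allclose(V[1:], 0.25 * 0.5 ** np.arange(1, 5), rtol=1e-12)

    def test_assortment_slows_decay(self):
        _, V0 = expected_ancestry_moments("hi", 0.5, 0.0, 6)
        _, V9 = expected_ancestry_moments("hi", 0.5, 0.9, 6)
        assert np.all(V9[1:] > V0[1:])
        # P=1 would freeze the variance entirely
        _, V1 = expected_ancestry_moments("hi", 0.5, 1.0, 6)
        np.testing.assert_allclose(V1, 0.25, rtol=1e-12)

    def test_cgf_reaches_target_mean_exactly(self):
        for p, T in [(0.25, 3), (0.5, 7), (0.8, 12)]:
            E, V = expected_ancestry_moments("cgf", p=p, P=0.0, T=T)
            assert E[0] == 0.0 and V[0] == 0.0
            assert E[-1] == pytest.approx(p, rel=1e-12)
            assert np.all(np.diff(E) > 0)

    def test_segregation_correction_adds_a_floor(self):
        _, V_cont = expected_ancestry_moments("hi", 0.5, 0.0, 15)
        _, V_fin = expected_ancestry_moments("hi", 0.5, 0.0, 15, n_loci=100)
        # at t=1 the pre-reproduction variance still equals E(1-E), so the
        # segregation term first appears at t=2
        assert V_fin[1] == pytest.approx(V_cont[1], rel=1e-12)
        assert np.all(V_fin[2:] > V_cont[2:])
        # late generations approach the fixed point of
        # v = v/2 + (E(1-E) - v)/(2m)  ->  v* = E(1-E)/(m+1)
        fixed = 0.25 / 101.0
        assert V_fin[-1] == pytest.approx(fixed, rel=0.02)

    def test_hi_recursion_matches_simulation(self, arch_divergent):
        # finite-locus corrected recursion vs 10 simulated trajectories
        reps = 10
        T = 3
        vals = np.zeros((reps, T + 1))
        for r in range(reps):
            cfg = SimulationConfig(model="hi", p=0.5, P=0.0, T=T, n=1500, seed=300 + r)
            traj = simulate_admixture(cfg, arch_divergent, keep="all")
            vals[r] = [ancestry_moments(c)[1] for c in traj]
        _, V = expected_ancestry_moments(
            "hi", 0.5, 0.0, T, n_loci=arch_divergent.m
        )
        mean = vals.mean(axis=0)
        se = vals.std(axis=0, ddof=1) / np.sqrt(reps)
        # V_0 has its own sampling error ~ sqrt(2/n) * 0.25
        se[0] = max(se[0], 1e-3)
        assert np.all(np.abs(mean - V) <= 3 * se)

    def test_cgf_recursion_matches_simulation(self, arch_divergent):
        reps = 8
        T = 5
        e = np.zeros((reps, T + 1))
        v = np.zeros((reps, T + 1))
        for r in range(reps):
            cfg = SimulationConfig(model="cgf", p=0.3, P=0.0, T=T, n=1500, seed=400 + r)
            traj = simulate_admixture(cfg, arch_divergent, keep="all")
            mom = [ancestry_moments(c) for c in traj]
            e[r] = [x[0] for x in mom]
            v[r] = [x[1] for x in mom]
        E, V = expected_ancestry_moments("cgf", 0.3, 0.0, T, n_loci=arch_divergent.m)
        for sim, pred in ((e, E), (v, V)):
            mean = sim.mean(axis=0)
            se = np.maximum(sim.std(axis=0, ddof=1) / np.sqrt(reps), 1e-12)
            assert np.all(np.abs(mean[1:] - pred[1:]) <= 3 * se[1:] + 1e-4)

    def test_invalid_model(self):
        with pytest.raises(ValueError):
            expected_ancestry_moments("island", 0.5, 0.0, 3)


class TestOracles:
    def test_monte_carlo_oracle_matches_closed_form(self):
        rng = np.random.default_rng(50)
        for trial in range(5):
            fr = draw_source_frequencies(30, F=0.2, seed=60 + trial)
            beta = assign_effect_magnitudes(fr)
            crit = ["max_ld_contribution", "min_ld_contribution", "random"][trial % 3]
            arch = permute_signs_select(fr, beta, 50, crit, seed=70 + trial)
            Eth = float(rng.uniform(0.2, 0.8))
            Vth = float(rng.uniform(0.0, 0.8) * Eth * (1 - Eth))
            pred = variance_components(arch, Eth, Vth).total
            est, se = simulated_variance_oracle(
                arch, Eth, Vth, n=120_000, seed=80 + trial
            )
            assert abs(est - pred) <= 3 * se

    def test_he_decomposition_sums_to_the_slope(self, unstructured_genotypes):
        from admixherit.estimators import _he_slope

        rng = np.random.default_rng(90)
        X = unstructured_genotypes.astype(float)
        Z = (X - X.mean(axis=0))
        u = rng.normal(size=Z.shape[1])
        genic, ld = he_estimand_decomposition(u, Z)
        g = Z @ u
        K = Z @ Z.T / Z.shape[1]
        slope = _he_slope(g - g.mean(), K)
        assert genic + ld == pytest.approx(slope, rel=1e-10)

    def test_he_decomposition_requires_centered_columns(self, unstructured_genotypes):
        X = unstructured_genotypes.astype(float)
        with pytest.raises(ValueError):
            he_estimand_decomposition(np.ones(X.shape[1]), X)

    def test_no_directional_ld_means_no_ld_component(self, unstructured_genotypes):
        # random signs on unstructured genotypes: ld component ~ 0 on average
        rng = np.random.default_rng(91)
        X = unstructured_genotypes.astype(float)
        sd = X.std(axis=0)
        Z = (X - X.mean(axis=0)) / sd
        vals = []
        for _ in range(30):
            u = rng.choice([-1.0, 1.0], size=Z.shape[1]) / np.sqrt(Z.shape[1])
            vals.append(he_estimand_decomposition(u, Z)[1])
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean()) <= 3 * se + 1e-3
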