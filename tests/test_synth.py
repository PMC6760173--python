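"""Founder-mosaic haplotypes, Balding-Nichols drift and phenotype simulation."""

import numpy as np
import pytest

from transloci.errors import ConfigurationError, ScenarioError, SimulationError
from transloci.synth import (
    PhenotypeSimSpec,
    PopulationModel,
    ScenarioSpec,
    derive_population,
    make_scenario,
    simulate_ancestral_haplotypes,
    simulate_phenotype,
)

from conftest import make_panel


class TestAncestralPool:
    def test_deterministic_under_seed(self):
        model = PopulationModel(n_variants=50)
        a = simulate_ancestral_haplotypes(model, seed=5)
        b = simulate_ancestral_haplotypes(model, seed=5)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)
        assert a.variants.equals(b.variants)

    def test_zero_recombination_copies_founders(self):
        model = PopulationModel(n_variants=40, n_founders=2, recomb_rate=0.0,
                                n_ancestral_haplotypes=30)
        pool = simulate_ancestral_haplotypes(model, seed=1)
        founders = {tuple(row) for row in pool.haplotypes}
        assert len(founders) <= 2  # every haplotype is an exact founder copy

    def test_high_recombination_approaches_equilibrium(self):
        model = PopulationModel(n_variants=40, recomb_rate=1.0,
                                n_ancestral_haplotypes=2000, n_founders=20)
        pool = simulate_ancestral_haplotypes(model, seed=2)
        r = np.corrcoef(pool.haplotypes, rowvar=False)
        off = r[~np.eye(r.shape[0], dtype=bool)]
        assert np.nanmean(off**2) < 0.01

    def test_ld_decays_with_distance(self):
        model = PopulationModel(n_variants=100, n_ancestral_haplotypes=2000)
        pool = simulate_ancestral_haplotypes(model, seed=3)
        haps = pool.haplotypes[:, pool.haplotypes.std(axis=0) > 0]
        r2 = np.corrcoef(haps, rowvar=False) ** 2
        m = r2.shape[0]
        near = np.mean([r2[i, i + 1] for i in range(m - 1)])
        far = np.mean([r2[i, i + m // 2] for i in range(m - m // 2)])
        assert near > far

    def test_zero_founders_rejected(self):
        with pytest.raises(ConfigurationError, match="founder"):
            PopulationModel(n_founders=0)


class TestDerivePopulation:
    def test_f_zero_keeps_frequencies(self):
        pool = simulate_ancestral_haplotypes(PopulationModel(n_variants=30), seed=4)
        panel = derive_population(pool, 0.0, 200, seed=5)
        np.testing.assert_array_equal(panel.pop_freqs, pool.freqs)

    def test_drifted_mean_matches_ancestral(self):
        # E[Beta(p(1-F)/F, (1-p)(1-F)/F)] = p; check the mean over many variants
        model = PopulationModel(n_variants=10_000, n_ancestral_haplotypes=200,
                                recomb_rate=1.0)
        pool = simulate_ancestral_haplotypes(model, seed=6)
        panel = derive_population(pool, 0.1, 50, seed=7)
        p = pool.freqs
        mc_se = np.sqrt(np.mean(0.1 * p * (1 - p)) / p.size)
        assert abs(panel.pop_freqs.mean() - p.mean()) < 3 * mc_se

    def test_sample_frequencies_track_drifted_targets(self):
        pool = simulate_ancestral_haplotypes(
            PopulationModel(n_variants=200, n_ancestral_haplotypes=400), seed=8)
        panel = derive_population(pool, 0.2, 2000, seed=9)
        # realized frequencies should cluster around the drifted parameters
        resid = panel.freqs - panel.pop_freqs
        assert np.mean(np.abs(resid)) < 0.02

    def test_same_pool_different_seeds_same_keys(self):
        pool = simulate_ancestral_haplotypes(PopulationModel(n_variants=30), seed=10)
        a = derive_population(pool, 0.1, 100, seed=1)
        b = derive_population(pool, 0.1, 100, seed=2)
        assert a.variants.equals(b.variants)
        assert not np.allclose(a.freqs, b.freqs)

    def test_divergence_monotone_in_f(self):
        # mean squared frequency difference between two derived populations
        # grows with F (averaged over seeds)
        pool = simulate_ancestral_haplotypes(
            PopulationModel(n_variants=300, n_ancestral_haplotypes=400), seed=11)
        msd = []
        for f in (0.02, 0.1, 0.3):
            vals = []
            for seed in range(5):
                a = derive_population(pool, f, 400, seed=(seed, 0))
                b = derive_population(pool, f, 400, seed=(seed, 1))
                vals.append(np.mean((a.freqs - b.freqs) ** 2))
            msd.append(np.mean(vals))
        assert msd[0] < msd[1] < msd[2]

    def test_too_few_samples_rejected(self):
        pool = simulate_ancestral_haplotypes(PopulationModel(n_variants=10), seed=12)
        with pytest.raises(ConfigurationError):
            derive_population(pool, 0.1, 1, seed=0)


class TestPhenotype:
    def test_pure_noise_variance(self, rng):
        x = rng.binomial(2, 0.4, size=5000)
        panel = make_panel(x[:, None])
        y = simulate_phenotype(panel, PhenotypeSimSpec(beta=0.0, causal_index=0, seed=1))
        # Var(y) = sigma^2; MC SE of a variance estimate ~ sigma^2 sqrt(2/n)
        assert abs(y.var() - 1.0) < 3 * np.sqrt(2 / 5000)

    def test_hwe_variance_closed_form(self, rng):
        n = 20_000
        x = rng.binomial(2, 0.3, size=n)
        panel = make_panel(x[:, None])
        y = simulate_phenotype(panel, PhenotypeSimSpec(beta=0.25, causal_index=0, seed=2))
        expected = 0.25**2 * 2 * 0.3 * 0.7 + 1.0  # 1.02625
        assert abs(y.var() - expected) < 3 * expected * np.sqrt(2 / n)

    def test_beta_recovered_by_regression(self, rng):
        n = 10_000
        x = rng.binomial(2, 0.35, size=n).astype(float)
        panel = make_panel(x[:, None])
        y = simulate_phenotype(panel, PhenotypeSimSpec(beta=0.2, causal_index=0, seed=3))
        xc = x - x.mean()
        slope = xc @ y / (xc @ xc)
        se = np.sqrt(1.0 / (xc @ xc))
        assert abs(slope - 0.2) < 3 * se

    def test_deterministic_under_seed(self, rng):
        panel = make_panel(rng.binomial(2, 0.5, size=(100, 2)).astype(float))
        spec = PhenotypeSimSpec(beta=0.3, causal_index=1, seed=9)
        np.testing.assert_array_equal(
            simulate_phenotype(panel, spec), simulate_phenotype(panel, spec)
        )

    def test_monomorphic_causal_rejected(self):
        panel = make_panel(np.ones((50, 1)))
        with pytest.raises(SimulationError, match="monomorphic"):
            simulate_phenotype(panel, PhenotypeSimSpec(beta=0.1, causal_index=0, seed=0))


class TestScenario:
    def test_shared_causal_is_shared(self, panel_pair):
        ref, tgt = panel_pair
        scen = make_scenario(ScenarioSpec(kind="shared", beta=0.25), ref, tgt, seed=1)
        assert scen.causal_target == scen.causal_ref
        assert scen.causal_r2 == 1.0
        # the strongest target association should be in LD with the causal
        x = tgt.dosages
        xc = (x - x.mean(0)) / x.std(0)
        yc = (scen.y_target - scen.y_target.mean()) / scen.y_target.std()
        z = xc.T @ yc / np.sqrt(len(yc))
        top = int(np.argmax(np.abs(z)))
        r = np.corrcoef(x[:, top], x[:, scen.causal_ref])[0, 1]
        assert r**2 > 0.1

    def test_distinct_in_window_respects_ceiling(self, panel_pair):
        ref, tgt = panel_pair
        spec = ScenarioSpec(kind="distinct", beta=0.25, max_r2_distinct=0.2,
                            distinct_mode="in_window")
        scen = make_scenario(spec, ref, tgt, seed=2)
        assert scen.causal_target != scen.causal_ref
        assert scen.causal_r2 < 0.2

    def test_distinct_unlinked_draws_external_causal(self, panel_pair):
        ref, tgt = panel_pair
        spec = ScenarioSpec(kind="distinct", beta=0.25, distinct_mode="unlinked")
        scen = make_scenario(spec, ref, tgt, seed=3)
        assert scen.causal_target is None
        assert scen.x_target_causal.shape == (tgt.n_samples,)

    def test_no_candidate_pair_raises(self):
        # two founders, no recombination: all polymorphic variants are in
        # perfect LD, so no pair can sit below the ceiling
        model = PopulationModel(n_variants=20, n_founders=2, recomb_rate=0.0,
                                n_ancestral_haplotypes=200)
        pool = simulate_ancestral_haplotypes(model, seed=13)
        a = derive_population(pool, 0.0, 300, seed=1)
        keep = np.flatnonzero(a.dosages.std(0) > 0)
        a = a.subset_variants(keep)
        b = derive_population(pool, 0.0, 300, seed=2).subset_variants(keep)
        spec = ScenarioSpec(kind="distinct", beta=0.2, max_r2_distinct=0.2,
                            distinct_mode="in_window")
        with pytest.raises(ScenarioError, match="ceiling"):
            make_scenario(spec, a, b, seed=4)

    @pytest.mark.parametrize("beta", [0.10, 0.15, 0.20, 0.25])
    def test_effect_size_grid_accepted(self, panel_pair, beta):
        ref, tgt = panel_pair
        scen = make_scenario(ScenarioSpec(kind="shared", beta=beta), ref, tgt, seed=5)
        assert scen.spec.beta == beta
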