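"""Single-causal likelihoods, the colocalization statistic and its permutation test."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import kstest, multivariate_normal

from transloci.assoc import LdMatrix, regularize_ld
from transloci.coloc import (
    STATUS_MHC,
    STATUS_NO_COMPLEMENT,
    STATUS_OK,
    STATUS_SINGLE_SNP,
    STATUS_TOO_FEW,
    ColocInput,
    in_mhc,
    jlim_lambda,
    permutation_p,
    run_coloc,
    single_causal_likelihood,
)
from transloci.io import VariantKey
from transloci.synth import ScenarioSpec, make_scenario
from transloci.transferability import Locus

from conftest import make_panel


def brute_force_lambda(l1, l2, r2_1, r2_2, lead, theta):
    """Literal loop over the definition: the independent oracle."""
    m = len(l1)
    total = 0.0
    any_term = False
    for i in range(m):
        if r2_1[lead][i] < theta:
            continue
        best = None
        for j in range(m):
            if r2_2[i][j] < theta:
                denom = l1[i] * l2[j]
                if best is None or denom > best:
                    best = denom
        if best is None:
            continue
        any_term = True
        total += l1[i] * np.log((l1[i] * l2[i]) / best)
    return total, any_term


def random_instance(rng, m):
    """A random window: correlated dosages -> likelihoods + LD."""
    base = rng.normal(size=(40, m))
    mix = rng.uniform(0.2, 0.9)
    for j in range(1, m):
        base[:, j] = mix * base[:, j - 1] + (1 - mix) * base[:, j]
    r2_1 = np.corrcoef(base, rowvar=False) ** 2
    r2_2 = np.corrcoef(base + rng.normal(scale=0.5, size=base.shape), rowvar=False) ** 2
    l1 = single_causal_likelihood(rng.normal(scale=2, size=m))
    l2 = single_causal_likelihood(rng.normal(scale=2, size=m))
    lead = int(rng.integers(m))
    return l1, l2, r2_1, r2_2, lead


class TestLikelihood:
    def test_equal_z_gives_uniform(self):
        l = single_causal_likelihood(np.array([1.7, 1.7, 1.7, 1.7]))
        np.testing.assert_allclose(l, 0.25, atol=1e-12)

    def test_three_snp_example(self):
        # L proportional to (e^4.5, 1, 1)
        l = single_causal_likelihood(np.array([3.0, 0.0, 0.0]))
        np.testing.assert_allclose(l, [0.978265, 0.010868, 0.010868], atol=5e-6)

    def test_profile_mvn_oracle_agrees(self, rng):
        # brute force: maximize the full MVN density over the non-centrality
        # for each candidate causal variant, then normalize
        for _ in range(10):
            m = 5
            a = rng.normal(size=(30, m))
            r = regularize_ld(np.corrcoef(a, rowvar=False), ridge=1e-6)
            z = rng.normal(scale=1.5, size=m)
            mvn = multivariate_normal(mean=np.zeros(m), cov=r)
            logs = []
            for i in range(m):
                obj = lambda lam: -multivariate_normal(
                    mean=lam * r[:, i], cov=r).logpdf(z)
                res = minimize_scalar(obj, bounds=(-50, 50), method="bounded")
                logs.append(-res.fun)
            logs = np.array(logs)
            oracle = np.exp(logs - logs.max())
            oracle /= oracle.sum()
            np.testing.assert_allclose(
                single_causal_likelihood(z), oracle, atol=1e-6)

    def test_normalized(self, rng):
        assert single_causal_likelihood(rng.normal(size=9)).sum() == pytest.approx(1.0)


class TestLambda:
    def hand_instance(self):
        l1 = np.array([0.7, 0.2, 0.1])
        l2 = np.array([0.6, 0.3, 0.1])
        r2 = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.1], [0.1, 0.1, 1.0]])
        return l1, l2, r2

    def test_three_snp_worked_example(self):
        # terms: 0.7*log(0.6/0.1) + 0.2*log(0.3/0.1) = 1.47395
        l1, l2, r2 = self.hand_instance()
        lam, status = jlim_lambda(l1, l2, r2, r2, lead=0, theta=0.8)
        assert status == STATUS_OK
        assert lam == pytest.approx(1.4740, abs=5e-5)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            m = int(rng.integers(2, 7))
            l1, l2, r2_1, r2_2, lead = random_instance(rng, m)
            lam, status = jlim_lambda(l1, l2, r2_1, r2_2, lead, theta=0.8)
            expected, any_term = brute_force_lambda(l1, l2, r2_1, r2_2, lead, 0.8)
            if status == STATUS_OK:
                assert any_term
                assert lam == pytest.approx(expected, abs=1e-10)
            else:
                assert not any_term

    def test_shared_signal_positive(self):
        l1, _, r2 = self.hand_instance()
        l2 = np.array([0.98, 0.01, 0.01])  # mass on the lead itself
        lam, _ = jlim_lambda(l1, l2, r2, r2, lead=0, theta=0.8)
        assert lam > 0

    def test_distinct_signal_negative(self):
        l1, _, r2 = self.hand_instance()
        l2 = np.array([0.01, 0.01, 0.98])  # mass outside the lead's class
        lam, _ = jlim_lambda(l1, l2, r2, r2, lead=0, theta=0.8)
        assert lam < 0

    def test_single_variant_window_fails(self):
        lam, status = jlim_lambda(np.array([1.0]), np.array([1.0]),
                                  np.ones((1, 1)), np.ones((1, 1)), 0)
        assert status == STATUS_SINGLE_SNP and np.isnan(lam)

    def test_no_complement_fails(self):
        l = np.array([0.5, 0.5])
        ones = np.ones((2, 2))
        lam, status = jlim_lambda(l, l, ones, ones, 0)
        assert status == STATUS_NO_COMPLEMENT and np.isnan(lam)


def coloc_input(panel, y, lead, theta=0.8, z1=None):
    r = np.corrcoef(panel.dosages, rowvar=False)
    if z1 is None:
        z1 = np.zeros(panel.n_variants)
    return ColocInput(
        z1=z1,
        ld1=LdMatrix(variants=panel.variant_keys(), r=r),
        target_dosages=panel.dosages,
        target_phenotype=y,
        lead=lead,
        theta=theta,
    )


class TestPermutation:
    def test_add_one_floor_under_strong_signal(self, panel_pair):
        ref, tgt = panel_pair
        scen = make_scenario(ScenarioSpec(kind="shared", beta=0.6), ref, tgt, seed=3)
        xs = (ref.dosages - ref.dosages.mean(0)) / ref.dosages.std(0)
        ys = (scen.y_ref - scen.y_ref.mean()) / scen.y_ref.std()
        z1 = xs.T @ ys / np.sqrt(ref.n_samples)
        inp = coloc_input(tgt, scen.y_target, lead=int(np.argmax(np.abs(z1))), z1=z1)
        inp.ld1 = LdMatrix(variants=None, r=np.corrcoef(ref.dosages, rowvar=False))
        res = permutation_p(inp, n_permutations=200, seed=1)
        assert res.status == STATUS_OK
        assert res.p_jlim == pytest.approx(1 / 201)
        assert res.lambda_stat > 0

    def test_null_p_uniform_over_runs(self, rng):
        # small window, pure-noise target phenotype: p should be uniform
        base = rng.normal(size=(120, 12))
        for j in range(1, 12):
            base[:, j] = 0.7 * base[:, j - 1] + 0.3 * base[:, j]
        dosage = np.clip(np.round(1 + base / 2), 0, 2)
        keep = dosage.std(0) > 0
        panel = make_panel(dosage[:, keep])
        z1 = rng.normal(scale=2, size=panel.n_variants)
        pvals = []
        for k in range(200):
            y = rng.normal(size=panel.n_samples)
            res = permutation_p(coloc_input(panel, y, lead=0, z1=z1),
                                n_permutations=100, seed=k)
            if res.status == STATUS_OK:
                pvals.append(res.p_jlim)
        assert len(pvals) > 150
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_invariant_to_variant_relabeling(self, panel_pair, rng):
        ref, tgt = panel_pair
        scen = make_scenario(ScenarioSpec(kind="shared", beta=0.3), ref, tgt, seed=5)
        z1 = rng.normal(scale=1.5, size=tgt.n_variants)
        lead = 4
        inp = coloc_input(tgt, scen.y_target, lead=lead, z1=z1)
        res = permutation_p(inp, n_permutations=150, seed=7)
        perm = rng.permutation(tgt.n_variants)
        tgt2 = tgt.subset_variants(perm)
        inp2 = coloc_input(tgt2, scen.y_target,
                           lead=int(np.flatnonzero(perm == lead)[0]), z1=z1[perm])
        res2 = permutation_p(inp2, n_permutations=150, seed=7)
        assert res2.lambda_stat == pytest.approx(res.lambda_stat, abs=1e-10)
        assert res2.p_jlim == res.p_jlim

    def test_too_few_permutations_rejected(self, panel_pair):
        _, tgt = panel_pair
        inp = coloc_input(tgt, np.random.default_rng(0).normal(size=tgt.n_samples), 0)
        with pytest.raises(Exception, match="100"):
            permutation_p(inp, n_permutations=10)


class TestRunColoc:
    def make_ref_stats(self, panel, y):
        from transloci.assoc import score_test_scan

        return score_test_scan(panel, y)

    def test_mhc_locus_excluded(self, panel_pair):
        ref, tgt = panel_pair
        locus = Locus(VariantKey("6", 30_000_000, "A", "G"), "HDL", 1e-150)
        res = run_coloc(locus, pd.DataFrame(columns=["chrom", "pos", "z"]),
                        ref, tgt, np.zeros(tgt.n_samples))
        assert res.status == STATUS_MHC

    def test_mhc_interval_bounds(self):
        assert in_mhc("6", 28_477_797, 28_477_797)
        assert in_mhc("chr6", 33_448_354, 33_500_000)
        assert not in_mhc("6", 33_448_355, 34_000_000)
        assert not in_mhc("8", 30_000_000, 30_050_000)

    def test_shared_locus_runs_ok(self, panel_pair):
        ref, tgt = panel_pair
        scen = make_scenario(ScenarioSpec(kind="shared", beta=0.5), ref, tgt, seed=9)
        stats = self.make_ref_stats(ref, scen.y_ref)
        lead_row = stats.loc[stats["p"].idxmin()]
        locus = Locus(
            VariantKey(str(lead_row["chrom"]), int(lead_row["pos"]),
                       str(lead_row["ref"]), str(lead_row["alt"])),
            "TG", 1e-150)
        res = run_coloc(locus, stats, ref, tgt, scen.y_target,
                        n_permutations=200, seed=1)
        assert res.status == STATUS_OK
        assert res.n_window_variants >= 5

    def test_sparse_window_fails_with_diagnostic(self, panel_pair):
        ref, tgt = panel_pair
        sparse_ref = ref.subset_variants(range(3))
        sparse_tgt = tgt.subset_variants(range(3))
        y = np.random.default_rng(0).normal(size=tgt.n_samples)
        stats = self.make_ref_stats(sparse_ref, np.random.default_rng(1).normal(size=ref.n_samples))
        lead_row = stats.iloc[0]
        locus = Locus(VariantKey(str(lead_row["chrom"]), int(lead_row["pos"]),
                                 "A", "G"), "TG", 1e-150)
        res = run_coloc(locus, stats, sparse_ref, sparse_tgt, y)
        assert res.status == STATUS_TOO_FEW
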