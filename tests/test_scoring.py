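"""PRS computation, evaluation metrics, LRT comparison and baselines."""

import numpy as np
import pytest

from annopred.scoring import (
    PVALUE_GRID,
    R2_GRID,
    baseline_prs,
    compute_prs,
    evaluate,
    greedy_prune,
    lrt_compare,
    tune_split,
)
from annopred.simulate import SimScenario, sim_panel, sim_trait, sumstats_from_panel
from annopred.stratified_ldsc import banded_r2


class TestComputePrs:
    def test_zero_weights_zero_scores(self, small_study):
        gp = small_study["panel"]
        np.testing.assert_array_equal(compute_prs(gp, np.zeros(gp.m_snp)), 0.0)

    def test_single_weight_recovers_column(self, small_study):
        gp = small_study["panel"]
        w = np.zeros(gp.m_snp)
        w[3] = 1.0
        np.testing.assert_allclose(compute_prs(gp, w), gp.standardized()[:, 3], rtol=1e-5)

    def test_true_weights_noise_free_trait_cor_one(self):
        scen = SimScenario(n_ind=300, m_snp=150, m_causal=30, h2=1.0, seed=21, k_annot=0)
        gp = sim_panel(scen)
        pheno, beta = sim_trait(gp, scen)
        scores = compute_prs(gp, beta)
        assert evaluate(scores, pheno)["cor"] == pytest.approx(1.0, abs=1e-6)


class TestEvaluate:
    def test_perfect_scores(self):
        labels = np.array([1, 1, 0, 1, 0, 0], float)
        m = evaluate(labels.copy(), labels)
        assert m["cor"] == pytest.approx(1.0)
        assert m["auc"] == pytest.approx(1.0)
        assert m["top5pct_case_frac"] == pytest.approx(1.0)

    def test_worked_pair_counting_example(self):
        # pair-count oracle: cases {3,2,0}, controls {1,-1,-2};
        # concordant pairs 8 of 9 -> AUC = 8/9
        scores = np.array([3, 2, 1, 0, -1, -2], float)
        labels = np.array([1, 1, 0, 1, 0, 0], float)
        cases = scores[labels == 1]
        controls = scores[labels == 0]
        oracle = np.mean([
            1.0 if c > d else 0.5 if c == d else 0.0 for c in cases for d in controls
        ])
        assert oracle == pytest.approx(8 / 9)
        assert evaluate(scores, labels)["auc"] == pytest.approx(oracle)

    def test_random_scores_auc_half(self, rng):
        labels = (rng.random(4000) < 0.5).astype(float)
        aucs = [
            evaluate(rng.standard_normal(4000), labels)["auc"] for _ in range(5)
        ]
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_constant_scores_warn_cor_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            m = evaluate(np.ones(10), np.arange(10.0))
        assert m["cor"] == 0.0

    def test_cor_affine_auc_monotone_invariance(self, rng):
        s = rng.standard_normal(200)
        y = (s + rng.standard_normal(200) > 0).astype(float)
        base = evaluate(s, y)
        aff = evaluate(3.0 * s - 7.0, y)
        mono = evaluate(np.exp(s), y)
        assert aff["cor"] == pytest.approx(base["cor"])
        assert aff["auc"] == pytest.approx(base["auc"])
        assert mono["auc"] == pytest.approx(base["auc"])


class TestTuneSplit:
    def test_single_candidate_equals_half_average(self, rng):
        y = rng.standard_normal(200)
        s = y + rng.standard_normal(200)
        out = tune_split(s, y, ["only"], seed=0)
        expect = np.mean([h["cor"] for h in out["half_metrics"]])
        assert out["metrics"]["cor"] == pytest.approx(expect)
        assert out["chosen"] == ["only", "only"]

    def test_planted_best_candidate_recovered(self, rng):
        y = rng.standard_normal(400)
        good = y + 0.3 * rng.standard_normal(400)
        bad1 = rng.standard_normal(400)
        bad2 = 0.1 * y + rng.standard_normal(400)
        out = tune_split(np.column_stack([bad1, good, bad2]), y, ["b1", "good", "b2"], seed=1)
        assert out["chosen"] == ["good", "good"]

    def test_binary_split_stratified(self, rng):
        y = np.zeros(100)
        y[:7] = 1  # rare cases: naive halving could lose all cases
        s = y + rng.standard_normal(100)
        out = tune_split(s, y, ["x"], seed=3)
        assert np.isfinite(out["metrics"]["cor"])


class TestLrtCompare:
    def test_duplicate_score_adds_nothing(self, rng):
        y = (rng.random(300) < 0.5).astype(float)
        s = rng.standard_normal(300) + y
        out = lrt_compare(s, s.copy(), y)
        assert out["p_add_2"] == pytest.approx(1.0, abs=1e-6)

    def test_null_addition_not_significant_on_average(self, rng):
        ps = []
        for _ in range(10):
            y = (rng.random(400) < 0.5).astype(float)
            s1 = y + rng.standard_normal(400)
            s2 = rng.standard_normal(400)  # independent of y given nothing
            ps.append(lrt_compare(s1, s2, y)["p_add_2"])
        assert np.mean(ps) > 0.2  # roughly uniform, not piled near 0

    def test_informative_addition_detected(self, rng):
        hits = 0
        for _ in range(10):
            g = rng.standard_normal(500)
            y = (g + rng.standard_normal(500) > 0).astype(float)
            s1 = g + 2.0 * rng.standard_normal(500)  # noisy PRS
            s2 = g  # the true genetic value
            if lrt_compare(s1, s2, y)["p_add_2"] < 0.05:
                hits += 1
        assert hits >= 6

    def test_continuous_phenotype_rejected(self, rng):
        with pytest.raises(ValueError):
            lrt_compare(rng.random(10), rng.random(10), rng.random(10))


class TestBaselines:
    def _study(self, h2=0.8, seed=31, n=800, m=300):
        scen = SimScenario(n_ind=n, m_snp=m, m_causal=15, h2=h2, seed=seed,
                           ld_rho=0.0, ld_block_len=1, k_annot=0)
        gp = sim_panel(scen)
        pheno, beta = sim_trait(gp, scen)
        gp.pheno = pheno
        ss = sumstats_from_panel(gp, pheno)
        return gp, ss, pheno

    def test_grids_match_stated_values(self):
        assert PVALUE_GRID == (1, 0.3, 0.1, 0.03, 0.01, 3e-3, 1e-3, 3e-4, 1e-4,
                               3e-5, 1e-5, 1e-6, 1e-7, 5e-8, 1e-8)
        assert R2_GRID == tuple(np.round(np.arange(0, 1.0, 0.1), 1))

    def test_sig_empty_when_nothing_significant(self):
        gp, ss, pheno = self._study(h2=0.0, seed=32)
        res = baseline_prs(ss, gp, "sig", pheno=pheno)
        assert np.isnan(res.scores).all()
        assert np.isnan(res.metrics["cor"])

    def test_sig_scores_when_hits_exist(self):
        gp, ss, pheno = self._study(h2=0.9, seed=33)
        res = baseline_prs(ss, gp, "sig", pheno=pheno)
        if not np.isnan(res.scores).any():
            assert res.metrics["cor"] > 0.2

    def test_all_uses_marginal_weights(self):
        gp, ss, pheno = self._study()
        res = baseline_prs(ss, gp, "all", pheno=pheno)
        np.testing.assert_allclose(res.scores, compute_prs(gp, ss.beta), rtol=1e-5)
        assert res.metrics["cor"] > 0.3

    def test_pt_no_pruning_equals_all_at_loose_grid_point(self):
        # independent SNPs at r2 threshold 0.9 and p = 1: nothing is removed
        gp, ss, pheno = self._study()
        band = banded_r2(gp.standardized(), radius=10)
        keep = greedy_prune(band, ss.pvalues, 0.9)
        assert keep.all()
        w = np.where(keep & (ss.pvalues < 1.0), ss.beta, 0.0)
        np.testing.assert_allclose(w, ss.beta)

    def test_pt_tunes_and_reports_metrics(self):
        gp, ss, pheno = self._study()
        band = banded_r2(gp.standardized(), radius=10)
        res = baseline_prs(ss, gp, "p_t", r2_band=band, pheno=pheno, seed=5)
        assert "cor" in res.metrics
        assert res.metrics["cor"] > 0.3

    def test_greedy_prune_removes_correlated_neighbor(self, rng):
        col = rng.standard_normal(60)
        x = np.column_stack([col, col + 0.01 * rng.standard_normal(60), rng.standard_normal(60)])
        x = (x - x.mean(0)) / x.std(0)
        band = banded_r2(x.astype(np.float32), radius=2)
        keep = greedy_prune(band, np.array([0.001, 0.5, 0.2]), 0.2)
        np.testing.assert_array_equal(keep, [True, False, True])
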