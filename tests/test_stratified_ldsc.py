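"""Stratified LD scores, the tau regression and heritability estimation."""

import numpy as np
import pandas as pd
import pytest

from annopred.annotations import build_annotation_set
from annopred.io_formats import GenotypePanel
from annopred.simulate import SimScenario, sim_annotations, sim_panel, sim_trait, sumstats_from_panel
from annopred.stratified_ldsc import (
    MultiCollinearityError,
    banded_r2,
    enrichment_test,
    fit_heritability,
    fit_tau,
    per_snp_h2,
    stratified_ld_scores,
    total_h2,
)


def _panel_from_matrix(x):
    n, m = x.shape
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(m)],
            "chrom": "1",
            "pos": 1 + 1000 * np.arange(m),
            "a1": "A",
            "a2": "G",
        }
    )
    samples = pd.DataFrame({"fid": [str(i) for i in range(n)], "iid": [str(i) for i in range(n)]})
    return GenotypePanel(samples=samples, snps=snps, dosage=np.asarray(x, float))


class TestStratifiedLdScores:
    def test_orthogonal_snps_reduce_to_membership(self):
        from scipy.linalg import hadamard

        # mutually orthogonal mean-zero columns: every off-diagonal r is 0,
        # so the stratified LD score equals the membership matrix exactly
        x = hadamard(8)[:, 1:5].astype(float)
        gp = _panel_from_matrix(x)
        tracks = [np.array([1, 1, 0, 0], dtype=np.int8)]
        ann = build_annotation_set(4, tracks, min_class_size=1)
        ld = stratified_ld_scores(gp, ann, radius=10, unit="snp")
        np.testing.assert_allclose(ld, ann.membership.astype(float), atol=1e-6)

    def test_duplicated_snp_doubles_score(self, rng):
        col = rng.standard_normal(50)
        x = np.column_stack([col, col])
        gp = _panel_from_matrix(x)
        ann = build_annotation_set(2, [np.array([1, 1], dtype=np.int8)], min_class_size=1)
        ld = stratified_ld_scores(gp, ann, radius=5, unit="snp")
        np.testing.assert_allclose(ld, 2.0, atol=1e-10)

    def test_matches_double_loop_oracle(self, rng):
        x = rng.standard_normal((30, 5))
        gp = _panel_from_matrix(x)
        tracks = [np.array([1, 0, 1, 0, 1], dtype=np.int8)]
        ann = build_annotation_set(5, tracks, min_class_size=1)
        radius = 2
        ld = stratified_ld_scores(gp, ann, radius=radius, unit="snp")
        xs = gp.standardized().astype(float)
        oracle = np.zeros((5, 2))
        for i in range(5):
            for j in range(5):
                if abs(i - j) > radius:
                    continue
                r = np.corrcoef(xs[:, i], xs[:, j])[0, 1]
                for k, member in enumerate(ann.membership.T):
                    if member[j]:
                        oracle[i, k] += r * r
        np.testing.assert_allclose(ld, oracle, atol=1e-10)

    def test_bp_and_snp_windows_agree_on_uniform_spacing(self, rng):
        x = rng.standard_normal((40, 12))
        gp = _panel_from_matrix(x)  # 1 kb spacing
        ann = build_annotation_set(12, [])
        ld_snp = stratified_ld_scores(gp, ann, radius=3, unit="snp")
        ld_bp = stratified_ld_scores(gp, ann, radius=3000, unit="bp")
        np.testing.assert_allclose(ld_snp, ld_bp)

    def test_banded_r2_matches_ld_score(self, rng):
        x = rng.standard_normal((60, 20)).astype(np.float32)
        x = (x - x.mean(0)) / x.std(0)
        band = banded_r2(x, radius=4)
        gp = _panel_from_matrix(x)
        ann = build_annotation_set(20, [])
        ld = stratified_ld_scores(gp, ann, radius=4, unit="snp")
        np.testing.assert_allclose(band.sum(axis=1), ld[:, 0], rtol=1e-4)


class TestFitTau:
    def test_group_mean_oracle_disjoint_annotations(self, rng):
        # independent SNPs, identity LD: the WLS collapses to group means
        m, n = 600, 4000
        t1 = np.zeros(m, dtype=np.int8)
        t1[:200] = 1
        ann = build_annotation_set(m, [t1], min_class_size=1)
        ld = ann.membership.astype(float)  # identity-LD stratified scores
        tau_true = np.array([2e-5, 8e-5])
        var = ld @ tau_true
        chi2 = 1.0 + (n - 1) * var + rng.standard_normal(m) * 0.01
        tau, se, jk = fit_tau(chi2, ld, n)
        # closed form: tau0 = mean outside; tau1 = mean inside - tau0
        out_mean = (chi2[200:].mean() - 1) / (n - 1)
        in_mean = (chi2[:200].mean() - 1) / (n - 1)
        np.testing.assert_allclose(tau, [out_mean, in_mean - out_mean], atol=1e-9)

    def test_null_trait_taus_near_zero(self):
        scen = SimScenario(n_ind=800, m_snp=2000, m_causal=10, h2=0.0,
                           ld_rho=0.0, ld_block_len=1, seed=3)
        gp = sim_panel(scen)
        ann = sim_annotations(2000, k=2, fraction=0.1, seed=4)
        zs = []
        for rep in range(3):
            pheno, _ = sim_trait(gp, scen, ann, seed=rep)
            ss = sumstats_from_panel(gp, pheno)
            ld = stratified_ld_scores(gp, ann, radius=20, unit="snp")
            tau, se, _ = fit_tau(ss.chi2, ld, gp.n_ind)
            zs.append(tau / se)
        assert np.abs(np.mean(zs, axis=0)) .max() < 2.5

    def test_permutation_equivariance(self, rng):
        m, n = 300, 2000
        ld = np.column_stack([np.ones(m), rng.random(m)]) + rng.random((m, 2)) * 0.1
        chi2 = 1 + rng.random(m)
        tau, _, _ = fit_tau(chi2, ld, n)
        perm = rng.permutation(m)
        tau_p, _, _ = fit_tau(chi2[perm], ld[perm], n)
        np.testing.assert_allclose(tau, tau_p, rtol=1e-8)

    def test_collinear_design_raises(self, rng):
        m = 100
        halves = np.zeros(m, dtype=np.int8)
        halves[: m // 2] = 1
        ann = build_annotation_set(m, [halves, 1 - halves], min_class_size=1)
        ld = ann.membership.astype(float)  # col0 = col1 + col2 exactly
        with pytest.raises(MultiCollinearityError, match="collinear"):
            fit_tau(1 + rng.random(m), ld, 1000)


class TestPerSnpH2:
    def test_additivity_and_bookkeeping(self):
        t1 = np.array([1, 1, 0, 0], dtype=np.int8)
        t2 = np.array([1, 0, 1, 0], dtype=np.int8)
        ann = build_annotation_set(4, [t1, t2], min_class_size=1)
        tau = np.array([1e-5, 2e-5, 4e-5])
        h2 = per_snp_h2(ann, tau, h2_total=0.5)
        np.testing.assert_allclose(h2, [7e-5, 3e-5, 5e-5, 1e-5])
        # sum over SNPs equals sum_k tau_k * |S_k|
        sizes = ann.membership.sum(axis=0)
        assert h2.sum() == pytest.approx((tau * sizes).sum())

    def test_negative_sum_floored(self):
        ann = build_annotation_set(3, [np.array([1, 0, 0], dtype=np.int8)], min_class_size=1)
        h2 = per_snp_h2(ann, np.array([1e-6, -5e-6]), h2_total=0.3)
        assert h2[0] > 0
        assert h2[0] == pytest.approx(1e-9 * 0.3 / 3)


class TestTotalH2:
    def test_direct_formula(self):
        # mean chi2 1.5, N=1000, l_bar=1, M=100 -> 0.05
        chi2 = np.full(100, 1.5)
        assert total_h2(chi2, np.ones(100), 1000) == pytest.approx(0.05)

    def test_null_clamps_to_floor_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            h2 = total_h2(np.ones(50), np.ones(50), 1000)
        assert h2 == pytest.approx(0.001)


class TestEnrichment:
    def _fit(self, seed, enriched):
        scen = SimScenario(
            n_ind=1500, m_snp=4000, m_causal=200, h2=0.5,
            ld_rho=0.0, ld_block_len=1, seed=seed,
            allocation=(0.45, 0.45, 0.1) if enriched else (0.1, 0.1, 0.8),
        )
        gp = sim_panel(scen)
        ann = sim_annotations(4000, k=2, fraction=0.1, seed=seed + 1)
        pheno, _ = sim_trait(gp, scen, ann, seed=seed + 2)
        ss = sumstats_from_panel(gp, pheno)
        fit = fit_heritability(ss, gp, ann, radius=20, unit="snp", n_jackknife=60)
        return fit, ann

    def test_genome_fold_is_one_and_enriched_annotation_detected(self):
        fit, ann = self._fit(11, enriched=True)
        fold, p = enrichment_test(fit, ann)
        assert fold[0] == 1.0 and p[0] == 1.0
        # 45% of causals in a 10% annotation: strong enrichment
        assert fold[1] > 2.0
        assert p[1] < 0.05

    def test_fit_heritability_bundles_consistent_fields(self):
        fit, ann = self._fit(13, enriched=False)
        assert fit.ld_scores.shape == (4000, 3)
        assert np.all(fit.per_snp_h2 > 0)
        np.testing.assert_allclose(
            fit.per_snp_h2_raw, ann.membership.astype(float) @ fit.tau
        )
        assert 0.001 <= fit.h2_total <= 1.0
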