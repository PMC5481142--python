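"""Reusable simulation studies exercising the full pipeline.

Each study generates synthetic data at a stated scale, runs the
annotation-informed PRS together with the relevant baselines, and
returns summary numbers.  A fixed genotype panel is reused across trait
replicates within a study (traits, causal sets and sample splits are
re-drawn each replicate), mirroring a design where genotypes come from
a single cohort; LD is estimated once from the full panel and used as
the reference for LD scores, block LD and pruning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import priors as priors_mod
from . import scoring, simulate
from .annotations import AnnotationSet, build_annotation_set
from .posterior import block_ld, make_blocks, posterior_effects, enumerate_posterior, gibbs_block
from .priors import DEFAULT_P0_GRID
from .simulate import SimScenario
from .stratified_ldsc import banded_r2, fit_heritability, stratified_ld_scores, fit_tau, total_h2

__all__ = [
    "annopred_prs",
    "methods_comparison_study",
    "ldsc_recovery_study",
    "constant_enrichment_study",
    "sample_size_study",
    "gibbs_oracle_study",
]

#: LD window (in SNPs to each side) used for LD scores in simulations
SIM_LD_RADIUS = 50


def annopred_prs(
    ss,
    gp_valid,
    annotations: AnnotationSet,
    *,
    ld_scores=None,
    ld_blocks=None,
    p0_grid=DEFAULT_P0_GRID,
    variants=("variance", "fraction"),
    n_blocks: int = 3000,
    iters: int = 100,
    burnin: int = 60,
    radius: float = SIM_LD_RADIUS,
    unit: str = "snp",
    seed: int = 0,
):
    """Annotation-informed PRS with split-half tuning over (variant, p0).

    ``gp_valid`` supplies both the LD reference (unless ``ld_scores`` /
    ``ld_blocks`` are precomputed) and the phenotyped individuals used
    for tuning and evaluation.  With a genome-only ``annotations`` this
    is exactly the LDpred-style single-annotation model.
    """
    m = len(ss)
    n = float(np.median(ss.n))
    if ld_scores is None:
        ld_scores = stratified_ld_scores(gp_valid, annotations, radius=radius, unit=unit)
    if ld_blocks is None:
        ld_blocks = block_ld(gp_valid, make_blocks(m, n_blocks))
    member = annotations.membership
    cols = np.arange(member.shape[1])
    if member.shape[1] > 1 and np.all(member[:, 1:].sum(axis=1) == 1):
        cols = cols[1:]  # tracks partition the genome: genome column redundant
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tau_sub, tau_se_sub, _ = fit_tau(ss.chi2, ld_scores[:, cols], n)
        h2 = total_h2(ss.chi2, ld_scores[:, 0], n)
    tau = np.zeros(member.shape[1])
    tau[cols] = tau_sub
    raw = member.astype(float) @ tau
    floor = 1e-9 * h2 / m
    h2i = np.maximum(raw, floor)
    cand_scores, cand_params = [], []
    if annotations.k == 0:
        variants = ("variance",)  # both priors coincide when K = 0
    seed_seq = np.random.SeedSequence(seed)
    sub_seeds = seed_seq.spawn(len(variants) * len(p0_grid))
    si = 0
    for variant in variants:
        for p0 in p0_grid:
            if variant == "variance":
                prior = priors_mod.make_prior_variance(h2i, h2, p0)
            else:
                prior = priors_mod.make_prior_fraction(h2i, h2, p0, annotations)
            eff = posterior_effects(
                ss, ld_blocks, prior, n=n, iters=iters, burnin=burnin,
                seed=int(sub_seeds[si].generate_state(1)[0] % (2**31)),
            )
            si += 1
            cand_scores.append(scoring.compute_prs(gp_valid, eff.mean))
            cand_params.append({"variant": variant, "p0": p0})
    tuned = scoring.tune_split(
        np.column_stack(cand_scores), gp_valid.pheno, cand_params, seed=seed
    )
    tuned["h2_total"] = h2
    tuned["tau"] = tau
    return tuned


@dataclass
class _FixedPanelStudy:
    """Shared precomputation for replicate studies on one panel."""

    gp: object
    annotations: AnnotationSet
    ld_scores: np.ndarray
    genome_ld_scores: np.ndarray
    r2_band: np.ndarray
    boundaries: list

    @classmethod
    def build(cls, scenario: SimScenario, k_annot: int | None = None, seed: int = 0,
              n_blocks: int = 3000, annotations: AnnotationSet | None = None):
        gp = simulate.sim_panel(scenario, seed=seed)
        if annotations is None:
            k = scenario.k_annot if k_annot is None else k_annot
            annotations = simulate.sim_annotations(
                scenario.m_snp, k=k, fraction=scenario.annot_fraction, seed=seed + 1
            )
        ld = stratified_ld_scores(gp, annotations, radius=SIM_LD_RADIUS, unit="snp")
        r2b = banded_r2(gp.standardized(), radius=SIM_LD_RADIUS)
        return cls(
            gp=gp,
            annotations=annotations,
            ld_scores=ld,
            genome_ld_scores=ld[:, :1],
            r2_band=r2b,
            boundaries=make_blocks(scenario.m_snp, n_blocks),
        )


def _one_replicate(
    study: _FixedPanelStudy,
    scenario: SimScenario,
    rep_seed: int,
    p0_grid,
    iters: int,
    burnin: int,
    methods=("annopred", "ldpred", "all", "p_t"),
):
    """Simulate one trait, split, and score every requested method.

    70% of individuals provide the training summary statistics; the
    remaining 30% are the phenotyped validation cohort whose two halves
    drive the split-half tuning.
    """
    rng = np.random.default_rng(rep_seed)
    gp = study.gp
    pheno, beta_true = simulate.sim_trait(gp, scenario, study.annotations, seed=rng)
    train, valid = simulate.split_data(gp, pheno, fractions=(0.7, 0.3), seed=rep_seed + 1)
    ss = simulate.sumstats_from_panel(train, train.pheno)
    ld_blocks = block_ld(valid, study.boundaries)
    out = {}
    genome_only = build_annotation_set(gp.m_snp, [])
    if "annopred" in methods:
        out["annopred"] = annopred_prs(
            ss, valid, study.annotations,
            ld_scores=study.ld_scores, ld_blocks=ld_blocks,
            p0_grid=p0_grid, iters=iters, burnin=burnin, seed=rep_seed,
        )["metrics"]
    if "ldpred" in methods:
        out["ldpred"] = annopred_prs(
            ss, valid, genome_only,
            ld_scores=study.genome_ld_scores, ld_blocks=ld_blocks,
            p0_grid=p0_grid, iters=iters, burnin=burnin, seed=rep_seed,
        )["metrics"]
    if "all" in methods:
        res = scoring.baseline_prs(ss, valid, "all", pheno=valid.pheno)
        ab = scoring.tune_split(res.scores, valid.pheno, ["all"], seed=rep_seed)
        out["all"] = ab["metrics"]
    if "sig" in methods:
        res = scoring.baseline_prs(ss, valid, "sig", pheno=valid.pheno)
        if np.isnan(res.scores).any():
            out["sig"] = {"cor": np.nan}
        else:
            out["sig"] = scoring.tune_split(res.scores, valid.pheno, ["sig"], seed=rep_seed)["metrics"]
    if "p_t" in methods:
        res = scoring.baseline_prs(
            ss, valid, "p_t", r2_band=study.r2_band, pheno=valid.pheno, seed=rep_seed
        )
        out["p_t"] = res.metrics
    return out


def methods_comparison_study(
    n_train: int = 3000,
    m_snp: int = 10_000,
    m_causal: int = 100,
    h2: float = 0.5,
    n_rep: int = 20,
    seed: int = 0,
    p0_grid=DEFAULT_P0_GRID,
    iters: int = 100,
    burnin: int = 60,
    methods=("annopred", "ldpred", "all", "p_t"),
):
    """Enriched-causal comparison of the PRS methods.

    Causal SNPs are allocated one third to each of two random 10%
    annotations and one third to the rest of the genome; ``n_train`` is
    the 70% training share of the cohort.  Returns per-method COR arrays
    across replicates.
    """
    n_total = int(round(n_train / 0.7))
    scenario = SimScenario(
        n_ind=n_total, m_snp=m_snp, m_causal=m_causal, h2=h2, seed=seed
    )
    study = _FixedPanelStudy.build(scenario, seed=seed)
    cors = {m: [] for m in methods}
    root = np.random.SeedSequence(seed)
    for r, child in enumerate(root.spawn(n_rep)):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        res = _one_replicate(study, scenario, rep_seed, p0_grid, iters, burnin, methods)
        for m in methods:
            cors[m].append(res[m]["cor"])
    return {m: np.array(v) for m, v in cors.items()}


def ldsc_recovery_study(
    m_snp: int = 20_000,
    n_ind: int = 5_000,
    h2: float = 0.5,
    n_rep: int = 20,
    seed: int = 0,
    enrich=(1.0, 5.0, 2.0),
):
    """Parameter recovery for the stratified heritability regression.

    Two random 10% annotations; true tau has per-SNP contributions
    proportional to ``enrich`` (baseline, +annot1, +annot2) scaled so the
    total heritability equals ``h2``.  Effects are drawn from the
    additive per-SNP-variance model each replicate.  Returns the true
    tau, per-replicate estimates, jackknife SEs and heritability
    estimates.
    """
    scenario = SimScenario(
        n_ind=n_ind, m_snp=m_snp, ld_rho=0.0, ld_block_len=1, h2=h2, seed=seed
    )
    gp = simulate.sim_panel(scenario, seed=seed)
    ann = simulate.sim_annotations(m_snp, k=2, fraction=0.1, seed=seed + 1)
    member = ann.membership.astype(float)
    frac = member.mean(axis=0)
    base = h2 / (m_snp * (1.0 + frac[1] * (enrich[1] - 1) + frac[2] * (enrich[2] - 1)))
    tau_true = np.array([base, (enrich[1] - 1) * base, (enrich[2] - 1) * base])
    per_snp = member @ tau_true
    ld = stratified_ld_scores(gp, ann, radius=SIM_LD_RADIUS, unit="snp")
    xs = gp.standardized()
    taus, ses, h2s = [], [], []
    root = np.random.SeedSequence(seed + 7)
    for child in root.spawn(n_rep):
        rng = np.random.default_rng(child)
        beta = rng.standard_normal(m_snp) * np.sqrt(per_snp)
        g = xs @ beta.astype(np.float32)
        eps = rng.standard_normal(n_ind) * np.sqrt(1.0 - h2)
        y = g.astype(float) + eps
        ss = simulate.sumstats_from_panel(gp, y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tau, se, _ = fit_tau(ss.chi2, ld, n_ind)
            h2s.append(total_h2(ss.chi2, ld[:, 0], n_ind))
        taus.append(tau)
        ses.append(se)
    return {
        "tau_true": tau_true,
        "tau_hat": np.array(taus),
        "tau_se": np.array(ses),
        "h2_hat": np.array(h2s),
        "h2_true": h2,
    }


def constant_enrichment_study(
    m_snp: int = 10_000,
    n_train: int = 3000,
    h2: float = 0.5,
    p_causal: float = 0.01,
    n_rep: int = 20,
    seed: int = 0,
    p0_grid=(0.3, 0.1, 0.03, 0.01, 3e-3),
    iters: int = 100,
    burnin: int = 60,
    n_perm: int = 10_000,
):
    """Genome split into two random halves, causal SNPs uniform.

    Checks the reduction claim: per-SNP heritability estimates in the
    two halves agree, and the annotation-informed PRS is statistically
    indistinguishable from its genome-only special case (pooled
    permutation test on the replicate CORs).
    """
    n_total = int(round(n_train / 0.7))
    scenario, ann = simulate.constant_enrichment_scenario(
        m_snp, n_total, h2, p_causal, seed=seed
    )
    study = _FixedPanelStudy.build(scenario, seed=seed, annotations=ann)
    half_h2 = []
    half_se = []
    cors = {"annopred": [], "ldpred": []}
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_rep):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        res = _one_replicate(
            study, scenario, rep_seed, p0_grid, iters, burnin,
            methods=("annopred", "ldpred"),
        )
        cors["annopred"].append(res["annopred"]["cor"])
        cors["ldpred"].append(res["ldpred"]["cor"])
        # per-half per-SNP heritability from the stratified fit
        pheno, _ = simulate.sim_trait(study.gp, scenario, ann, seed=np.random.default_rng(rep_seed))
        train, _ = simulate.split_data(study.gp, pheno, fractions=(0.7, 0.3), seed=rep_seed + 1)
        ss = simulate.sumstats_from_panel(train, train.pheno)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tau, se, _ = fit_tau(ss.chi2, study.ld_scores[:, 1:], train.n_ind)
        half_h2.append(tau)
        half_se.append(se)
    perm_p = simulate.permutation_test(
        np.array(cors["annopred"]), np.array(cors["ldpred"]), n_perm=n_perm, seed=seed
    )
    return {
        "half_per_snp_h2": np.array(half_h2),
        "half_se": np.array(half_se),
        "true_per_snp_h2": h2 / m_snp,
        "cor_annopred": np.array(cors["annopred"]),
        "cor_ldpred": np.array(cors["ldpred"]),
        "perm_p": perm_p,
    }


def sample_size_study(
    m_snp: int = 6000,
    n_train: int = 1200,
    p_causal: float = 0.01,
    h2: float = 0.5,
    subset_fractions=(1.0, 0.5, 0.25),
    n_rep: int = 20,
    seed: int = 0,
    p0_grid=DEFAULT_P0_GRID,
    iters: int = 100,
    burnin: int = 60,
):
    """Effective-sample-size sweep at fixed heritability and sparsity.

    Traits are simulated from a shrinking leading subset of the SNPs
    (M_s = fraction * M) while the causal proportion and h2 within the
    subset stay fixed, mimicking a larger effective sample size
    N * M / M_s for the full-panel analysis.  Returns the mean COR of
    the annotation-informed PRS per effective size (ascending).
    """
    n_total = int(round(n_train / 0.7))
    base = SimScenario(n_ind=n_total, m_snp=m_snp, m_causal=1, h2=h2, seed=seed)
    study = _FixedPanelStudy.build(base, seed=seed)
    mean_cors = []
    eff = []
    for frac in subset_fractions:  # descending M_s -> ascending effective size
        ms = int(frac * m_snp)
        scenario = replace(
            base, m_causal=max(2, int(round(p_causal * ms))), causal_subset=ms
        )
        cors = []
        root = np.random.SeedSequence(seed + int(1000 * frac))
        for child in root.spawn(n_rep):
            rep_seed = int(child.generate_state(1)[0] % (2**31))
            res = _one_replicate(
                study, scenario, rep_seed, p0_grid, iters, burnin,
                methods=("annopred",),
            )
            cors.append(res["annopred"]["cor"])
        mean_cors.append(float(np.mean(cors)))
        eff.append(n_train * m_snp / ms)
    return {"effective_n": eff, "mean_cor": mean_cors}


def _mcse_ips(chain: np.ndarray) -> np.ndarray:
    """Monte-Carlo SE of each column mean by the initial positive sequence.

    Sums adjacent autocovariance pairs until a pair goes negative
    (Geyer's estimator for reversible chains; mildly conservative).
    """
    n, k = chain.shape
    centered = chain - chain.mean(axis=0)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(centered, nfft, axis=0)
    acov_all = np.fft.irfft(f * np.conj(f), nfft, axis=0)[:n].real / n
    out = np.empty(k)
    for j in range(k):
        acov = acov_all[:, j]
        sigma2 = acov[0]
        t = 1
        while t + 1 < min(n, 2000):
            pair = acov[t] + acov[t + 1]
            if pair <= 0:
                break
            sigma2 += 2.0 * pair
            t += 2
        out[j] = np.sqrt(max(sigma2, acov[0]) / n)
    return out


def gibbs_oracle_study(
    n_blocks: int = 100,
    max_size: int = 8,
    n_gwas: int = 1000,
    iters: int = 4000,
    burnin: int = 500,
    seed: int = 0,
):
    """Sampler-vs-enumeration check on random small blocks.

    Random PSD LD (sample correlation of a small Gaussian panel), random
    spike-and-slab priors of both kinds, data generated from the model.
    Monte-Carlo SEs use the initial-positive-sequence estimator on each
    coordinate's chain.  Returns per-coordinate |gibbs - exact| / MCSE
    z-scores.
    """
    rng = np.random.default_rng(seed)
    zs = []
    for b in range(n_blocks):
        s = int(rng.integers(1, max_size + 1))
        x = rng.standard_normal((60, s))
        d = np.corrcoef(x, rowvar=False) if s > 1 else np.ones((1, 1))
        d = np.atleast_2d(d)
        variant = "variance" if b % 2 == 0 else "fraction"
        if variant == "variance":
            p = np.full(s, float(rng.uniform(0.05, 1.0)))
            v = rng.uniform(0.5, 3.0, size=s) / (n_gwas * p)
        else:
            p = rng.uniform(0.05, 1.0, size=s)
            v = np.full(s, float(rng.uniform(0.5, 3.0)) / n_gwas)
        h2_b = min(float((p * v).sum()), 0.5)
        s2 = (1.0 - h2_b) / n_gwas
        beta = np.where(rng.random(s) < p, rng.standard_normal(s) * np.sqrt(v), 0.0)
        chol = np.linalg.cholesky(d + 1e-10 * np.eye(s))
        bh = d @ beta + np.sqrt(s2) * (chol @ rng.standard_normal(s))
        exact = enumerate_posterior(bh, d, p, v, s2)
        mean, _, draws = gibbs_block(
            bh, d, p, v, h2_b, n_gwas, iters=iters, burnin=burnin,
            seed=int(rng.integers(2**31)), track_draws=True,
        )
        mcse = np.maximum(_mcse_ips(draws), 1e-12)
        zs.append(np.abs(mean - exact) / mcse)
    return np.concatenate(zs)
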