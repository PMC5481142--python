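"""PRS computation, hyperparameter tuning, evaluation and baselines.

The score of individual i is PRS_i = sum_j x_ij * w_j on standardized
genotypes, with weights w_j either posterior mean effects (annotation
prior or its genome-only LDpred-style special case) or marginal effects
filtered by significance / pruning+thresholding for the baselines.

Hyperparameters are tuned by a split-half scheme on the validation
cohort: pick the candidate maximizing the correlation between PRS and
phenotype (COR) on one half, evaluate on the other, swap roles, and
average the two held-out metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .io_formats import GenotypePanel, SummaryStats

__all__ = [
    "PRSResult",
    "compute_prs",
    "evaluate",
    "tune_split",
    "lrt_compare",
    "greedy_prune",
    "baseline_prs",
    "PVALUE_GRID",
    "R2_GRID",
]

#: p-value thresholds tuned over for the pruning+thresholding baseline
PVALUE_GRID = (
    1, 0.3, 0.1, 0.03, 0.01, 3e-3, 1e-3, 3e-4, 1e-4, 3e-5, 1e-5, 1e-6, 1e-7, 5e-8, 1e-8,
)
#: LD r^2 pruning thresholds tuned over
R2_GRID = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)

#: genome-wide significance threshold for the significant-SNP baseline
GENOME_WIDE_SIG = 5e-8


@dataclass
class PRSResult:
    """Per-individual scores plus the parameters and metrics behind them."""

    scores: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)


def compute_prs(gp: GenotypePanel, weights) -> np.ndarray:
    """PRS_i = sum_j x_ij * w_j on the standardized dosage matrix."""
    w = np.asarray(weights, float)
    if w.shape[0] != gp.m_snp:
        raise ValueError("weights not aligned with panel SNPs")
    return gp.standardized() @ w.astype(np.float32)


def evaluate(scores, pheno, top_pct: float = 5.0) -> dict:
    """COR, AUC (binary phenotypes) and top-percentile case enrichment.

    COR is the Pearson correlation between PRS and the phenotype on its
    observed scale (0/1 for case-control).  Constant scores give COR 0
    with a warning.  top{k}pct_case_frac is the case proportion among
    the k% of individuals with the highest scores.
    """
    scores = np.asarray(scores, float)
    pheno = np.asarray(pheno, float)
    if scores.shape != pheno.shape:
        raise ValueError("scores and phenotype are not aligned")
    out: dict = {}
    if np.ptp(scores) == 0 or np.ptp(pheno) == 0:
        warnings.warn("constant scores or phenotype: COR set to 0", stacklevel=2)
        out["cor"] = 0.0
    else:
        out["cor"] = float(np.corrcoef(scores, pheno)[0, 1])
    binary = set(np.unique(pheno)) <= {0.0, 1.0}
    if binary and 0 < pheno.sum() < pheno.size:
        out["auc"] = float(roc_auc_score(pheno, scores)) if np.ptp(scores) > 0 else 0.5
        n_top = max(1, int(round(scores.size * top_pct / 100.0)))
        top = np.argsort(scores)[::-1][:n_top]
        out[f"top{top_pct:g}pct_case_frac"] = float(pheno[top].mean())
    return out


def _split_halves(pheno, rng, max_tries=20):
    """Random half split, stratified re-splits until both halves are usable."""
    n = pheno.size
    binary = set(np.unique(pheno)) <= {0.0, 1.0}
    for attempt in range(max_tries):
        if binary and attempt > 0:
            # stratified: split cases and controls separately
            a = []
            for cls in (0.0, 1.0):
                idx = np.flatnonzero(pheno == cls)
                idx = rng.permutation(idx)
                a.append(idx[: idx.size // 2])
            a = np.sort(np.concatenate(a))
        else:
            a = np.sort(rng.permutation(n)[: n // 2])
        b = np.setdiff1d(np.arange(n), a)
        ok = all(
            (np.ptp(pheno[h]) > 0 if not binary else len(set(pheno[h])) == 2)
            for h in (a, b)
        )
        if ok:
            return a, b
    raise ValueError("could not find a non-degenerate half split")


def tune_split(score_matrix, pheno, params: list, seed: int | None = 0) -> dict:
    """Split-half tuning: select by COR on one half, evaluate on the other.

    ``score_matrix`` is (n_ind, n_candidates); ``params`` labels the
    candidates.  Returns the averaged held-out metrics and the candidate
    chosen on each half.
    """
    s = np.asarray(score_matrix, float)
    if s.ndim == 1:
        s = s[:, None]
    pheno = np.asarray(pheno, float)
    rng = np.random.default_rng(seed)
    a, b = _split_halves(pheno, rng)
    halves = [(a, b), (b, a)]
    chosen, held = [], []
    for sel, ev in halves:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cors = [evaluate(s[sel, j], pheno[sel])["cor"] for j in range(s.shape[1])]
        j = int(np.argmax(cors))
        chosen.append(params[j])
        held.append(evaluate(s[ev, j], pheno[ev]))
    avg = {
        k: float(np.mean([h[k] for h in held])) for k in held[0] if k in held[1]
    }
    return {"metrics": avg, "chosen": chosen, "half_metrics": held}


def lrt_compare(scores_1, scores_2, pheno) -> dict:
    """Nested logistic likelihood-ratio test of added predictive value.

    Fits pheno ~ PRS1 and pheno ~ PRS1 + PRS2; the statistic 2 * delta
    log-likelihood is referred to chi-square(1).  Run in both orders;
    ``p_add_2`` tests whether PRS2 adds to PRS1 and vice versa.
    Perfect separation yields NaN.
    """
    import statsmodels.api as sm

    pheno = np.asarray(pheno, float)
    if not set(np.unique(pheno)) <= {0.0, 1.0}:
        raise ValueError("LRT comparison requires a binary phenotype")

    def _ll(cols):
        x = sm.add_constant(np.column_stack(cols))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(pheno, x).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(fit.params)):
                return np.nan
            return fit.llf
        except Exception:  # separation / non-convergence
            return np.nan

    out = {}
    for label, first, second in (
        ("p_add_2", scores_1, scores_2),
        ("p_add_1", scores_2, scores_1),
    ):
        # a collinear addition cannot change the likelihood: LRT stat is 0
        design = np.column_stack([np.ones_like(first), first, second])
        if np.linalg.matrix_rank(design) < 3:
            out[label] = 1.0
            continue
        ll0 = _ll([first])
        ll1 = _ll([first, second])
        if np.isnan(ll0) or np.isnan(ll1):
            out[label] = np.nan
        else:
            stat = max(0.0, 2.0 * (ll1 - ll0))
            out[label] = float(stats.chi2.sf(stat, df=1))
    return out


def greedy_prune(r2_band: np.ndarray, pvalues: np.ndarray, r2_thresh: float) -> np.ndarray:
    """LD clumping: keep SNPs in ascending p-value order.

    ``r2_band`` is the (M, 2r+1) banded r^2 matrix from
    ``stratified_ldsc.banded_r2``.  Visiting SNPs from smallest p, a
    retained SNP removes every not-yet-visited neighbour whose r^2 with
    it exceeds ``r2_thresh``.  Returns a boolean keep mask.
    """
    m, w = r2_band.shape
    radius = (w - 1) // 2
    alive = np.ones(m, bool)
    keep = np.zeros(m, bool)
    order = np.argsort(pvalues, kind="stable")
    for i in order:
        if not alive[i]:
            continue
        keep[i] = True
        alive[i] = False
        jlo = max(i - radius, 0)
        jhi = min(i + radius + 1, m)
        band = r2_band[i, jlo - i + radius : jhi - i + radius]
        kill = np.flatnonzero(band > r2_thresh) + jlo
        alive[kill] = False
    return keep


def baseline_prs(
    ss: SummaryStats,
    gp: GenotypePanel,
    method: str,
    r2_band: np.ndarray | None = None,
    pheno=None,
    seed: int | None = 0,
) -> PRSResult:
    """The three marginal-weight baselines: 'sig', 'all' and 'p_t'.

    * sig  - marginal effects of genome-wide significant SNPs (p < 5e-8);
      NaN scores when no SNP reaches significance.
    * all  - marginal effects of every shared SNP.
    * p_t  - pruning + thresholding, tuning the r^2 and p-value cutoffs
      by the split-half scheme (requires ``r2_band`` and ``pheno``).

    The LDpred-style baseline is the full pipeline with a genome-only
    annotation and is produced by the pipeline module, not here.
    """
    beta = ss.beta
    pv = ss.pvalues
    if method == "sig":
        mask = pv < GENOME_WIDE_SIG
        if not mask.any():
            return PRSResult(
                scores=np.full(gp.n_ind, np.nan),
                method="sig",
                metrics={"cor": np.nan},
                params={"note": "no SNP at genome-wide significance"},
            )
        w = np.where(mask, beta, 0.0)
        scores = compute_prs(gp, w)
        res = PRSResult(scores=scores, method="sig")
    elif method == "all":
        scores = compute_prs(gp, beta)
        res = PRSResult(scores=scores, method="all")
    elif method == "p_t":
        if r2_band is None or pheno is None:
            raise ValueError("p_t baseline needs r2_band and pheno for tuning")
        xs = gp.standardized()
        cand_scores, cand_params = [], []
        for r2t in R2_GRID:
            keep = greedy_prune(r2_band, pv, r2t)
            for pt in PVALUE_GRID:
                w = np.where(keep & (pv < pt), beta, 0.0)
                cand_scores.append(xs @ w.astype(np.float32))
                cand_params.append({"r2": r2t, "p": pt})
        tuned = tune_split(np.column_stack(cand_scores), pheno, cand_params, seed=seed)
        res = PRSResult(
            scores=np.full(gp.n_ind, np.nan),
            method="p_t",
            params={"chosen": tuned["chosen"]},
            metrics=tuned["metrics"],
        )
        return res
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    if pheno is not None:
        res.metrics = evaluate(res.scores, np.asarray(pheno, float))
    return res
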