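"""Annotation-stratified LD score regression and heritability partitioning.

Under the additive model beta_i ~ N(0, sum_{j: i in S_j} tau_j) for
standardized genotypes, the expected association chi-square satisfies

    E(N * beta_hat_i^2) ~= (N - 1) * sum_k tau_k * l(i, k) + 1,

where l(i, k) = sum_{j in window(i), j in S_k} r_ij^2 is the stratified
LD score.  tau is fitted by weighted least squares with the intercept
fixed at 1; standard errors come from a contiguous-block jackknife.  The
total chip heritability is estimated by the summary-statistic
approximation to the Haseman-Elston estimator,
H2 = M * (mean_chi2 - 1) / (N * mean_ld_score).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .annotations import AnnotationSet
from .io_formats import GenotypePanel, SummaryStats

logger = logging.getLogger(__name__)

__all__ = [
    "HeritabilityFit",
    "MultiCollinearityError",
    "stratified_ld_scores",
    "fit_tau",
    "per_snp_h2",
    "total_h2",
    "enrichment_test",
    "fit_heritability",
    "banded_r2",
]

#: per-SNP heritability floor, as a fraction of the average per-SNP share
H2_FLOOR_FRACTION = 1e-9


class MultiCollinearityError(ValueError):
    """The stratified design matrix is rank deficient.

    Highly overlapping annotation tracks produce correlated LD-score
    columns; multi-collinearity makes the per-annotation coefficients
    numerically unstable or unidentifiable.
    """


@dataclass
class HeritabilityFit:
    """Fitted heritability partition."""

    tau: np.ndarray  # (K+1,) per-annotation per-SNP heritability contribution
    tau_se: np.ndarray  # jackknife SEs
    ld_scores: np.ndarray  # (M, K+1)
    per_snp_h2: np.ndarray  # floored per-SNP heritabilities
    per_snp_h2_raw: np.ndarray  # pre-floor values sum_{j:i in S_j} tau_j
    h2_total: float
    n: float
    jackknife_tau: np.ndarray = field(repr=False)  # (n_blocks, K+1) delete-block taus


def _window_bounds(positions, chrom, radius, unit, m):
    """Per-SNP [lo, hi) window bounds over same-chromosome neighbours."""
    idx = np.arange(m)
    if unit == "snp":
        lo = np.maximum(idx - int(radius), 0)
        hi = np.minimum(idx + int(radius) + 1, m)
    elif unit == "bp":
        pos = np.asarray(positions, float)
        lo = np.searchsorted(pos, pos - radius, side="left")
        hi = np.searchsorted(pos, pos + radius, side="right")
    else:
        raise ValueError("unit must be 'snp' or 'bp'")
    if chrom is not None:
        chrom = np.asarray(chrom)
        # restrict windows to runs of the same chromosome
        change = np.flatnonzero(chrom[1:] != chrom[:-1]) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [m]])
        run_start = np.repeat(starts, ends - starts)
        run_end = np.repeat(ends, ends - starts)
        lo = np.maximum(lo, run_start)
        hi = np.minimum(hi, run_end)
    return lo, hi


def stratified_ld_scores(
    gp: GenotypePanel,
    annotations: AnnotationSet,
    radius: float = 1_000_000,
    unit: str = "bp",
    adjust: bool = False,
    chunk: int = 512,
) -> np.ndarray:
    """l(i, k): windowed sum of r^2 with SNPs in annotation S_k.

    r^2 is the squared sample correlation in the (standardized) panel and
    includes the SNP itself, so l(i, 0) >= 1.  ``adjust`` applies the
    small-sample correction r^2 - (1 - r^2) / (N - 2).
    """
    if radius <= 0:
        raise ValueError("window radius must be > 0")
    x = gp.standardized()
    n, m = x.shape
    member = annotations.membership.astype(np.float32)
    if member.shape[0] != m:
        raise ValueError("annotation set not aligned with panel")
    lo, hi = _window_bounds(
        gp.snps["pos"].to_numpy(), gp.snps["chrom"].to_numpy(), radius, unit, m
    )
    out = np.empty((m, member.shape[1]), dtype=np.float64)
    col = np.arange(m)
    # exact per-column scales: the float32 standardization leaves variances
    # at 1 only to single precision, but the windowed sums must match an
    # exact pairwise-r^2 computation to near machine precision
    inv_norm = 1.0 / np.sqrt(np.einsum("ij,ij->j", x, x, dtype=np.float64) / n)
    for c0 in range(0, m, chunk):
        c1 = min(c0 + chunk, m)
        wlo, whi = lo[c0:c1].min(), hi[c0:c1].max()
        r = (x[:, c0:c1].T.astype(np.float64) @ x[:, wlo:whi].astype(np.float64)) / n
        r *= inv_norm[c0:c1, None]
        r *= inv_norm[None, wlo:whi]
        r2 = r * r
        if adjust:
            r2 = r2 - (1.0 - r2) / (n - 2)
        j = col[wlo:whi][None, :]
        inwin = (j >= lo[c0:c1, None]) & (j < hi[c0:c1, None])
        out[c0:c1] = (r2 * inwin) @ member[wlo:whi]
    return out


def banded_r2(x_std: np.ndarray, radius: int, chunk: int = 1024) -> np.ndarray:
    """Squared correlations with the +-radius SNP neighbourhood.

    Returns (M, 2*radius + 1) with column ``radius`` the self-r^2 (= 1);
    entries falling outside the chromosome are 0.  Shared helper for LD
    pruning and window diagnostics.
    """
    n, m = x_std.shape
    w = 2 * radius + 1
    out = np.zeros((m, w), dtype=np.float32)
    for c0 in range(0, m, chunk):
        c1 = min(c0 + chunk, m)
        wlo = max(c0 - radius, 0)
        whi = min(c1 + radius, m)
        r = (x_std[:, c0:c1].T @ x_std[:, wlo:whi]) / n
        r2 = (r * r).astype(np.float32)
        for i in range(c0, c1):
            jlo, jhi = max(i - radius, 0), min(i + radius + 1, m)
            out[i, jlo - i + radius : jhi - i + radius] = r2[i - c0, jlo - wlo : jhi - wlo]
    return out


def fit_tau(
    chi2: np.ndarray,
    ld_scores: np.ndarray,
    n: float,
    weights: np.ndarray | None = None,
    n_jackknife: int = 200,
):
    """Weighted least squares for the heritability-partition coefficients.

    Regresses chi2 - 1 on (N - 1) * l(i, k) with no intercept (the
    intercept of the chi-square regression is fixed at its null value 1).
    Default weights are 1 / max(1, l(i, 0))^2.  Returns (tau, tau_se,
    jackknife_tau) with delete-one-block estimates from ``n_jackknife``
    contiguous SNP blocks.
    """
    chi2 = np.asarray(chi2, float)
    ld = np.asarray(ld_scores, float)
    m, p = ld.shape
    if m <= p:
        raise ValueError("need more SNPs than annotation categories")
    if weights is None:
        weights = 1.0 / np.maximum(1.0, ld[:, 0]) ** 2
    design = (n - 1.0) * ld
    y = chi2 - 1.0
    sw = np.sqrt(weights)
    xw = design * sw[:, None]
    rank = np.linalg.matrix_rank(xw)
    if rank < p:
        raise MultiCollinearityError(
            "stratified LD-score design is rank deficient; annotation tracks "
            "are collinear (multi-collinearity) -- drop or merge overlapping tracks"
        )
    yw = y * sw
    xtx = xw.T @ xw
    xty = xw.T @ yw
    tau = np.linalg.solve(xtx, xty)

    n_blocks = min(n_jackknife, m)
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    jk = np.empty((n_blocks, p))
    for b in range(n_blocks):
        s = slice(edges[b], edges[b + 1])
        xtx_b = xw[s].T @ xw[s]
        xty_b = xw[s].T @ yw[s]
        jk[b] = np.linalg.solve(xtx - xtx_b, xty - xty_b)
    tau_se = np.sqrt((n_blocks - 1) / n_blocks * ((jk - jk.mean(0)) ** 2).sum(0))
    return tau, tau_se, jk


def per_snp_h2(
    annotations: AnnotationSet, tau: np.ndarray, h2_total: float | None = None
) -> np.ndarray:
    """Per-SNP heritability sum_{j: i in S_j} tau_j, floored to stay positive.

    WLS can produce negative tau sums for individual SNPs; the floor
    (a vanishing fraction of the average per-SNP share) keeps the prior
    proper.
    """
    raw = annotations.membership.astype(float) @ np.asarray(tau, float)
    if h2_total is None:
        h2_total = max(raw.sum(), 1e-3)
    floor = H2_FLOOR_FRACTION * h2_total / annotations.m_snp
    n_floored = int((raw < floor).sum())
    if n_floored:
        logger.info("floored %d per-SNP heritabilities", n_floored)
    return np.maximum(raw, floor)


def total_h2(chi2: np.ndarray, ld0: np.ndarray, n: float, m: int | None = None) -> float:
    """Chip heritability M * (mean_chi2 - 1) / (N * mean LD score).

    Clamped to [0.001, 1] (with a warning) so downstream priors remain
    proper even for null traits.
    """
    chi2 = np.asarray(chi2, float)
    ld0 = np.asarray(ld0, float)
    if m is None:
        m = chi2.size
    lbar = ld0.mean()
    if lbar <= 0:
        raise ValueError("mean LD score must be positive")
    h2 = m * (chi2.mean() - 1.0) / (n * lbar)
    if not 0.001 <= h2 <= 1.0:
        warnings.warn(
            f"heritability estimate {h2:.4g} outside [0.001, 1]; clamped", stacklevel=2
        )
        h2 = float(np.clip(h2, 0.001, 1.0))
    return float(h2)


def enrichment_test(fit: HeritabilityFit, annotations: AnnotationSet):
    """Fold enrichment of heritability per annotation with jackknife p-values.

    fold_k = (share of total per-SNP heritability in S_k) / (share of
    SNPs in S_k); the p-value is a two-sided z-test of fold != 1 using
    the block-jackknife SE of the fold.  The genome category has fold 1
    by definition.
    """
    member = annotations.membership.astype(float)
    m, k1 = member.shape
    snp_share = member.mean(axis=0)
    small = snp_share < 0.01
    if small[1:].any():
        warnings.warn(
            "annotation(s) with <1% of SNPs: enrichment SEs will be wide",
            stacklevel=2,
        )
    overlap = member.T @ member  # |S_k ∩ S_j|

    def folds(tau):
        h2_in = overlap @ tau  # sum of per-SNP h2 inside each S_k
        tot = float(member[:, 0] @ (member @ tau))
        return (h2_in / tot) / snp_share

    fold = folds(fit.tau)
    jk = np.array([folds(t) for t in fit.jackknife_tau])
    nb = jk.shape[0]
    if nb < 30:
        warnings.warn("fewer than 30 jackknife blocks; p-values unreliable", stacklevel=2)
    se = np.sqrt((nb - 1) / nb * ((jk - jk.mean(0)) ** 2).sum(0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (fold - 1.0) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    fold[0], p[0] = 1.0, 1.0  # whole genome: enrichment 1 by definition
    return fold, p


def fit_heritability(
    ss: SummaryStats,
    gp: GenotypePanel,
    annotations: AnnotationSet,
    radius: float = 1_000_000,
    unit: str = "bp",
    n_jackknife: int = 200,
    adjust_r2: bool = False,
) -> HeritabilityFit:
    """End-to-end heritability partition from harmonized inputs."""
    ld = stratified_ld_scores(gp, annotations, radius=radius, unit=unit, adjust=adjust_r2)
    n = float(np.median(ss.n))
    chi2 = ss.chi2
    tau, tau_se, jk = fit_tau(chi2, ld, n, n_jackknife=n_jackknife)
    h2 = total_h2(chi2, ld[:, 0], n)
    raw = annotations.membership.astype(float) @ tau
    return HeritabilityFit(
        tau=tau,
        tau_se=tau_se,
        ld_scores=ld,
        per_snp_h2=per_snp_h2(annotations, tau, h2),
        per_snp_h2_raw=raw,
        h2_total=h2,
        n=n,
        jackknife_tau=jk,
    )
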