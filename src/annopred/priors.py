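"""Annotation-informed empirical priors on SNP effect sizes.

Two spike-and-slab priors built from the per-SNP heritability partition:

* **per-SNP variance** (variant 1): every SNP is causal with the same
  probability p0 but the slab variance is proportional to its estimated
  per-SNP heritability,
  beta_i ~ p0 * N(0, sigma_i^2 / p0) + (1 - p0) * delta_0, with
  sigma_i^2 = c * h2_i and c chosen so sum_i sigma_i^2 = H2.

* **per-combination causal fraction** (variant 2): a common causal-effect
  variance V = H2 / (p0 * M) but annotation-combination classes carry
  different causal fractions p_T = p0 * M * H_T^2 / (M_T * H2), where
  H_T^2 is the class's share of the estimated heritability.

Under both, the total heritability implied by the prior equals the
chip-heritability estimate H2; with a single (genome-only) annotation
both collapse to the classic uniform spike-and-slab, so the pipeline
reduces to an LDpred-style model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .annotations import AnnotationSet

logger = logging.getLogger(__name__)

__all__ = ["PriorSpec", "make_prior_variance", "make_prior_fraction", "DEFAULT_P0_GRID"]

#: default tuning grid for the overall causal proportion p0
DEFAULT_P0_GRID = (1.0, 0.3, 0.1, 0.03, 0.01, 3e-3, 1e-3, 3e-4, 1e-4)

#: lower clip for per-class causal fractions
P_FLOOR = 1e-6


@dataclass
class PriorSpec:
    """Per-SNP spike-and-slab mixture parameters.

    ``p_snp[i]`` is the prior causal probability and ``v_snp[i]`` the
    slab (causal-effect) variance of SNP i, so the prior expectation of
    beta_i^2 is p_snp[i] * v_snp[i].
    """

    variant: str  # "variance" or "fraction"
    p0: float
    p_snp: np.ndarray  # (M,) prior causal probability per SNP
    v_snp: np.ndarray  # (M,) slab variance per SNP
    h2_total: float
    sigma2: np.ndarray | None = None  # variant 1: per-SNP total prior variance
    c: float | None = None  # variant 1 scaling constant
    v_common: float | None = None  # variant 2 unclipped common slab variance

    @property
    def expected_h2(self) -> float:
        """Total heritability implied by the prior, sum_i p_i * v_i."""
        return float(np.sum(self.p_snp * self.v_snp))

    @property
    def per_block_h2(self):
        return self.p_snp * self.v_snp


def make_prior_variance(per_snp_h2, h2_total: float, p0: float) -> PriorSpec:
    """Variant 1: common causal fraction p0, annotation-scaled slab variance."""
    _check_p0(p0)
    h2i = np.asarray(per_snp_h2, float)
    if np.any(h2i <= 0):
        raise ValueError("per-SNP heritabilities must be positive (apply the floor)")
    total = h2i.sum()
    if total <= 0:
        raise ValueError("sum of per-SNP heritabilities must be positive")
    c = h2_total / total
    sigma2 = c * h2i
    return PriorSpec(
        variant="variance",
        p0=p0,
        p_snp=np.full(h2i.size, p0),
        v_snp=sigma2 / p0,
        h2_total=h2_total,
        sigma2=sigma2,
        c=c,
    )


def make_prior_fraction(
    per_snp_h2, h2_total: float, p0: float, annotations: AnnotationSet
) -> PriorSpec:
    """Variant 2: common slab variance, annotation-specific causal fractions.

    Classes whose computed fraction exceeds 1 are clipped to 1 (and
    fractions below ``P_FLOOR`` raised to it); in either case the class's
    slab variance is rescaled so the class heritability H_T^2 = p_T *
    M_T * V is preserved.
    """
    _check_p0(p0)
    h2i = np.asarray(per_snp_h2, float)
    m0 = h2i.size
    if annotations.m_snp != m0:
        raise ValueError("annotation set not aligned with per-SNP heritabilities")
    combo = annotations.combo_id
    n_classes = annotations.n_classes
    m_t = annotations.combo_sizes.astype(float)
    if np.any(m_t == 0):
        raise ValueError("empty annotation-combination class")
    class_h2 = np.bincount(combo, weights=h2i, minlength=n_classes)
    h2_t = class_h2 / h2i.sum() * h2_total  # class share of total heritability
    v = h2_total / (p0 * m0)
    p_t = p0 * m0 * h2_t / (m_t * h2_total)
    clipped = np.clip(p_t, P_FLOOR, 1.0)
    v_t = np.full(n_classes, v)
    adjust = clipped != p_t
    if adjust.any():
        logger.info("clipped causal fraction in %d classes", int(adjust.sum()))
        # keep H_T^2 = p_T * M_T * V_T after clipping
        v_t[adjust] = h2_t[adjust] / (clipped[adjust] * m_t[adjust])
    return PriorSpec(
        variant="fraction",
        p0=p0,
        p_snp=clipped[combo],
        v_snp=v_t[combo],
        h2_total=h2_total,
        v_common=v,
    )


def _check_p0(p0: float) -> None:
    if not 0 < p0 <= 1:
        raise ValueError("p0 must lie in (0, 1]")
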