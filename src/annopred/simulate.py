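"""Synthetic genotype panels, annotations and traits.

The generator emulates the structure of the study design the pipeline is
built for: standardized common-variant genotypes with block LD, K binary
annotations covering fixed genome fractions, causal SNPs enriched inside
the annotations, Gaussian causal effects N(0, h2/m), and a quantitative
(or liability-threshold binary) trait.  Defaults follow the evaluated
designs: two annotations covering 10% of the genome each, one third of
the causal SNPs placed in each annotation and the rest in the
complement, heritability 0.25 or 0.5, and 300 or 3000 causal variants
at genome scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import AnnotationSet, build_annotation_set
from .io_formats import GenotypePanel, SummaryStats

__all__ = [
    "SimScenario",
    "sim_panel",
    "sim_annotations",
    "sim_trait",
    "sumstats_from_panel",
    "split_data",
    "permutation_test",
    "constant_enrichment_scenario",
]


@dataclass
class SimScenario:
    """Parameters of one synthetic study."""

    n_ind: int
    m_snp: int
    ld_rho: float = 0.5  # latent (copula) correlation within an LD block
    ld_block_len: int = 10  # SNPs per LD block; 1 = independent SNPs
    maf_range: tuple = (0.05, 0.5)
    k_annot: int = 2
    annot_fraction: float = 0.1
    m_causal: int = 300
    h2: float = 0.5
    allocation: tuple = (1 / 3, 1 / 3, 1 / 3)  # causal shares: A1, A2, complement
    uniform_causals: bool = False  # ignore allocation; causals uniform genome-wide
    causal_subset: int | None = None  # restrict causal SNPs to the first M_s SNPs
    binary: bool = False
    prevalence: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must lie in [0, 1)")
        if not 0 <= self.h2 <= 1:
            raise ValueError("h2 must lie in [0, 1]")
        if self.m_causal > self.m_snp:
            raise ValueError("m_causal cannot exceed m_snp")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sim_panel(scenario: SimScenario, seed=None) -> GenotypePanel:
    """Draw a diploid dosage panel with block LD via a Gaussian copula.

    Each haplotype allele is 1{Phi(z) < f} for a latent Gaussian z with
    equicorrelation ``ld_rho`` inside contiguous blocks of
    ``ld_block_len`` SNPs, giving Binomial(2, f) marginals with positive
    within-block dosage correlation.  Deterministic given the seed.
    """
    rng = _rng(scenario.seed if seed is None else seed)
    n, m = scenario.n_ind, scenario.m_snp
    maf = rng.uniform(*scenario.maf_range, size=m)
    thresh = stats.norm.ppf(maf)
    rho = scenario.ld_rho
    blen = max(1, scenario.ld_block_len)
    dosage = np.zeros((n, m), dtype=np.float32)
    for hap in range(2):
        z = rng.standard_normal((n, m)).astype(np.float32)
        if rho > 0 and blen > 1:
            n_blocks = (m + blen - 1) // blen
            shared = rng.standard_normal((n, n_blocks)).astype(np.float32)
            shared = np.repeat(shared, blen, axis=1)[:, :m]
            z = np.sqrt(1 - rho, dtype=np.float32) * z + np.sqrt(
                rho, dtype=np.float32
            ) * shared
        dosage += (z < thresh.astype(np.float32)).astype(np.float32)
    snps = pd.DataFrame(
        {
            "snp_id": [f"rs{i+1}" for i in range(m)],
            "chrom": "1",
            "pos": 1 + 1000 * np.arange(m, dtype=np.int64),
            "a1": "A",
            "a2": "G",
        }
    )
    samples = pd.DataFrame(
        {"fid": [f"F{i+1}" for i in range(n)], "iid": [f"I{i+1}" for i in range(n)]}
    )
    return GenotypePanel(samples=samples, snps=snps, dosage=dosage)


def sim_annotations(
    m_snp: int, k: int = 2, fraction: float = 0.1, seed=0, min_class_size: int = 10
) -> AnnotationSet:
    """K binary tracks, each an exact-size uniform-random genome fraction."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    rng = _rng(seed)
    size = int(fraction * m_snp)
    tracks = []
    for _ in range(k):
        t = np.zeros(m_snp, dtype=np.int8)
        t[rng.choice(m_snp, size=size, replace=False)] = 1
        tracks.append(t)
    return build_annotation_set(m_snp, tracks, min_class_size=min_class_size)


def _pick_causals(scenario: SimScenario, annotations: AnnotationSet | None, rng):
    m, mc = scenario.m_snp, scenario.m_causal
    ms = m if scenario.causal_subset is None else int(scenario.causal_subset)
    if scenario.uniform_causals or annotations is None or annotations.k == 0:
        return rng.choice(ms, size=mc, replace=False)
    member = annotations.membership[:ms]
    k = annotations.k
    regions = [np.flatnonzero(member[:, j + 1] == 1) for j in range(k)]
    complement = np.flatnonzero(member[:, 1:].sum(axis=1) == 0)
    alloc = np.asarray(scenario.allocation, float)
    if alloc.size != k + 1:
        raise ValueError("allocation must have one share per annotation plus complement")
    counts = np.floor(alloc / alloc.sum() * mc).astype(int)
    counts[-1] = mc - counts[:-1].sum()
    chosen: list[np.ndarray] = []
    for region, cnt in zip(regions + [complement], counts):
        pool = np.setdiff1d(region, np.concatenate(chosen) if chosen else [])
        if cnt > pool.size:
            raise ValueError("not enough SNPs in a region for its causal allocation")
        chosen.append(rng.choice(pool, size=cnt, replace=False))
    return np.sort(np.concatenate(chosen))


def sim_trait(
    gp: GenotypePanel,
    scenario: SimScenario,
    annotations: AnnotationSet | None = None,
    seed=None,
):
    """Simulate a trait: Y = X beta + eps on standardized genotypes.

    Causal effects are N(0, h2/m_causal); the noise is rescaled
    empirically so the realized genetic variance share equals h2.
    Returns (pheno, beta_true).  With ``scenario.binary`` the quantitative
    value acts as a liability and cases are the top ``prevalence``
    fraction.
    """
    rng = _rng(scenario.seed + 1 if seed is None else seed)
    m = gp.m_snp
    beta = np.zeros(m)
    if scenario.h2 > 0 and scenario.m_causal > 0:
        causal = _pick_causals(scenario, annotations, rng)
        beta[causal] = rng.standard_normal(causal.size) * np.sqrt(
            scenario.h2 / scenario.m_causal
        )
    g = gp.standardized() @ beta.astype(np.float32)
    g = g.astype(float)
    var_g = g.var()
    if scenario.h2 >= 1.0:
        y = g
    elif scenario.h2 <= 0 or var_g == 0:
        y = rng.standard_normal(gp.n_ind)
    else:
        eps = rng.standard_normal(gp.n_ind)
        eps *= np.sqrt(var_g * (1.0 - scenario.h2) / scenario.h2) / eps.std()
        y = g + eps
    if scenario.binary:
        cut = np.quantile(y, 1.0 - scenario.prevalence)
        y = (y > cut).astype(float)
    else:
        y = (y - y.mean()) / y.std() if y.std() > 0 else y
    return y, beta


def sumstats_from_panel(gp: GenotypePanel, pheno) -> SummaryStats:
    """Marginal GWAS estimates beta_hat = X'Y / N on standardized data."""
    y = np.asarray(pheno, float)
    ys = (y - y.mean()) / y.std()
    bh = (gp.standardized().T @ ys.astype(np.float32)).astype(float) / gp.n_ind
    t = gp.snps.copy()
    t = t.rename(columns={"a1": "allele_eff", "a2": "allele_oth"})
    t["beta"] = bh
    t["n"] = gp.n_ind
    return SummaryStats(t[["snp_id", "chrom", "pos", "allele_eff", "allele_oth", "beta", "n"]])


def split_data(gp: GenotypePanel, pheno=None, fractions=(0.7, 0.15, 0.15), seed=0):
    """Disjoint train/tune/test individual subsets (default 70/15/15)."""
    fractions = np.asarray(fractions, float)
    if not np.isclose(fractions.sum(), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = _rng(seed)
    n = gp.n_ind
    perm = rng.permutation(n)
    cuts = np.cumsum(np.round(fractions[:-1] * n).astype(int))
    parts = np.split(perm, cuts)
    out = []
    for idx in parts:
        if idx.size < 50:
            import warnings

            warnings.warn(f"data split of only {idx.size} individuals", stacklevel=2)
        sub = gp.subset(ind_idx=np.sort(idx))
        if pheno is not None:
            sub.pheno = np.asarray(pheno, float)[np.sort(idx)]
        out.append(sub)
    return tuple(out)


def permutation_test(x, y, n_perm: int = 10_000, seed=0) -> float:
    """Pooled-relabeling test of equal mean prediction accuracy.

    The statistic is |mean(x) - mean(y)|; labels are reshuffled within
    the pooled sample ``n_perm`` times and the p-value is the fraction
    of permuted statistics strictly exceeding the observed one.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = _rng(seed)
    obs = abs(x.mean() - y.mean())
    pooled = np.concatenate([x, y])
    n = x.size
    # vectorized permutations in manageable batches
    count = 0
    batch = max(1, min(n_perm, int(2e7 // (2 * n))))
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        idx = np.argsort(rng.random((b, 2 * n)), axis=1)
        perm = pooled[idx]
        diff = np.abs(perm[:, :n].mean(axis=1) - perm[:, n:].mean(axis=1))
        count += int((diff > obs).sum())
        done += b
    return count / n_perm


def constant_enrichment_scenario(
    m_snp: int, n_ind: int, h2: float, p_causal: float, seed: int = 0, **kw
) -> tuple[SimScenario, AnnotationSet]:
    """Two complementary random annotation halves, causals uniform genome-wide.

    Under this design per-SNP heritability is constant (h2 / m per SNP in
    expectation regardless of annotation), so the annotation-informed
    prior collapses to the genome-only one and the pipeline should match
    its LDpred-style special case.
    """
    rng = _rng(seed)
    half = np.zeros(m_snp, dtype=np.int8)
    half[rng.choice(m_snp, size=m_snp // 2, replace=False)] = 1
    ann = build_annotation_set(m_snp, [half, 1 - half], names=["halfA", "halfB"])
    scen = SimScenario(
        n_ind=n_ind,
        m_snp=m_snp,
        m_causal=max(1, int(round(p_causal * m_snp))),
        h2=h2,
        uniform_causals=True,
        seed=seed,
        **kw,
    )
    return scen, ann
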