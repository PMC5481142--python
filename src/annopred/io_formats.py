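"""Readers, writers and SNP harmonization for the PRS pipeline.

Summary statistics are whitespace/tab-delimited text with configurable
column names; genotypes are PLINK 1 bed/bim/fam triplets (SNP-major bed).
``harmonize`` intersects the two sources, aligns effect alleles to the
panel's counted allele, and drops strand-ambiguous variants.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryStats",
    "GenotypePanel",
    "FormatError",
    "EmptyInputError",
    "read_sumstats",
    "write_sumstats",
    "read_genotypes",
    "write_genotypes",
    "harmonize",
    "exclude_region",
    "MHC_REGION",
]

#: MHC interval on chromosome 6 (bp, 1-based, closed) excluded in
#: sensitivity analyses of immune-mediated traits.
MHC_REGION = ("6", 28_477_797, 33_448_354)

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default column-name mapping for summary-statistic files
DEFAULT_COLUMN_MAP = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "allele_eff": "A1",
    "allele_oth": "A2",
    "beta": "BETA",
    "n": "N",
}


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class EmptyInputError(ValueError):
    """An input contains no usable records."""


@dataclass
class SummaryStats:
    """Per-SNP marginal association results from a GWAS.

    ``beta`` holds the marginal effect on the standardized scale
    (beta_hat = X'Y/N for standardized genotype and trait), so the
    association chi-square is simply N * beta_hat**2.
    """

    table: pd.DataFrame  # columns: snp_id chrom pos allele_eff allele_oth beta n

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_id(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def beta(self) -> np.ndarray:
        return self.table["beta"].to_numpy(float)

    @property
    def n(self) -> np.ndarray:
        return self.table["n"].to_numpy(float)

    @property
    def chi2(self) -> np.ndarray:
        """Association chi-square, N * beta_hat**2."""
        return self.n * self.beta**2

    @property
    def pvalues(self) -> np.ndarray:
        """Two-sided p-values from the z statistic sqrt(N)*beta_hat."""
        from scipy import stats

        return stats.chi2.sf(self.chi2, df=1)


@dataclass
class GenotypePanel:
    """Individual-level genotypes for a set of SNPs.

    dosage is individuals x SNPs, counting copies of the first bim allele
    (a1); missing genotypes are NaN.  ``standardized()`` mean-imputes
    missing values and scales every column to mean 0, variance 1.
    """

    samples: pd.DataFrame  # columns: fid iid (+ optional pheno)
    snps: pd.DataFrame  # columns: snp_id chrom pos a1 a2
    dosage: np.ndarray  # (n_ind, m_snp) float, NaN = missing
    pheno: np.ndarray | None = None
    _std_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_ind(self) -> int:
        return self.dosage.shape[0]

    @property
    def m_snp(self) -> int:
        return self.dosage.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP, missing genotypes ignored."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freq = np.nanmean(self.dosage, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    @property
    def monomorphic(self) -> np.ndarray:
        """Mask of SNPs with zero dosage variance (unusable after scaling)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            v = np.nanvar(self.dosage, axis=0)
        return ~(v > 0)

    def standardized(self) -> np.ndarray:
        """Mean-imputed, column-standardized dosage matrix (float32)."""
        if self._std_cache is None:
            x = np.asarray(self.dosage, dtype=np.float32).copy()
            mask = np.isnan(x)
            if mask.any():
                col_mean = np.nanmean(np.where(mask, np.nan, x), axis=0)
                x[mask] = np.broadcast_to(col_mean, x.shape)[mask]
            x -= x.mean(axis=0)
            sd = x.std(axis=0)
            if np.any(sd == 0):
                raise ValueError(
                    "monomorphic SNPs present; drop them before standardization"
                )
            x /= sd
            self._std_cache = x
        return self._std_cache

    def subset(self, snp_idx=None, ind_idx=None) -> "GenotypePanel":
        snp_idx = np.arange(self.m_snp) if snp_idx is None else np.asarray(snp_idx)
        ind_idx = np.arange(self.n_ind) if ind_idx is None else np.asarray(ind_idx)
        return GenotypePanel(
            samples=self.samples.iloc[ind_idx].reset_index(drop=True),
            snps=self.snps.iloc[snp_idx].reset_index(drop=True),
            dosage=self.dosage[np.ix_(ind_idx, snp_idx)],
            pheno=None if self.pheno is None else np.asarray(self.pheno)[ind_idx],
        )

    def drop_monomorphic(self) -> "GenotypePanel":
        mono = self.monomorphic
        if mono.any():
            logger.info("dropping %d monomorphic SNPs", int(mono.sum()))
            return self.subset(snp_idx=np.flatnonzero(~mono))
        return self


def read_sumstats(path, column_map: dict | None = None) -> SummaryStats:
    """Parse a delimited summary-statistics file.

    Rows with missing/invalid alleles, non-finite effects or N <= 0 are
    dropped (counts logged); duplicated SNP ids keep the first occurrence.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    try:
        raw = pd.read_csv(path, sep=r"\s+", dtype=str)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"could not parse summary statistics {path}: {exc}") from exc
    missing_cols = [v for v in cmap.values() if v not in raw.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing required columns {missing_cols}")
    df = pd.DataFrame(
        {
            "snp_id": raw[cmap["snp_id"]].astype(str),
            "chrom": raw[cmap["chrom"]].astype(str),
            "pos": pd.to_numeric(raw[cmap["pos"]], errors="coerce"),
            "allele_eff": raw[cmap["allele_eff"]].astype(str).str.upper(),
            "allele_oth": raw[cmap["allele_oth"]].astype(str).str.upper(),
            "beta": pd.to_numeric(raw[cmap["beta"]], errors="coerce"),
            "n": pd.to_numeric(raw[cmap["n"]], errors="coerce"),
        }
    )
    n0 = len(df)
    ok = (
        df["allele_eff"].isin(_VALID_ALLELES)
        & df["allele_oth"].isin(_VALID_ALLELES)
        & (df["allele_eff"] != df["allele_oth"])
        & np.isfinite(df["beta"])
        & (df["n"] > 0)
        & np.isfinite(df["pos"])
    )
    df = df[ok]
    if n0 - len(df):
        logger.info("dropped %d unusable summary-statistic rows", n0 - len(df))
    dup = df["snp_id"].duplicated()
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicated SNP ids; keeping first occurrence",
            stacklevel=2,
        )
        df = df[~dup]
    if df.empty:
        raise EmptyInputError(f"{path}: no usable summary-statistic rows")
    df["pos"] = df["pos"].astype(np.int64)
    return SummaryStats(df.reset_index(drop=True))


def write_sumstats(ss: SummaryStats, path) -> None:
    out = ss.table.rename(
        columns={
            "snp_id": "SNP",
            "chrom": "CHR",
            "pos": "BP",
            "allele_eff": "A1",
            "allele_oth": "A2",
            "beta": "BETA",
            "n": "N",
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PLINK 1 bed/bim/fam
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # v1.00, SNP-major

# 2-bit genotype codes in PLINK 1 bed, per SNP-major byte (LSB first):
# 00 -> hom a1 (2 copies), 10 -> het (1), 11 -> hom a2 (0), 01 -> missing
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def read_genotypes(prefix) -> GenotypePanel:
    """Read a PLINK 1 bed/bim/fam triplet; dosage counts the bim a1 allele."""
    prefix = Path(prefix)
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f)
    snps = pd.read_csv(
        bim,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )[["snp_id", "chrom", "pos", "a1", "a2"]]
    samples = pd.read_csv(
        fam,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(samples), len(snps)
    if n == 0 or m == 0:
        raise EmptyInputError(f"{prefix}: empty fam or bim")
    raw = np.fromfile(bed, dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise FormatError(f"{bed}: bad magic bytes (not a SNP-major PLINK 1 bed)")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * m:
        raise FormatError(f"{bed}: size inconsistent with {n} samples x {m} SNPs")
    codes = body.reshape(m, bytes_per_snp)
    # unpack 2-bit fields, individual-fastest within a byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    geno = (codes[:, :, None] >> shifts) & 0b11  # (m, bytes, 4)
    geno = geno.reshape(m, -1)[:, :n]
    dosage = _CODE_TO_DOSAGE[geno].T.copy()  # (n, m)
    pheno = samples["pheno"].to_numpy(float)
    # PLINK missing phenotype codes
    pheno_valid = np.isfinite(pheno) & (pheno != -9)
    use_pheno = pheno if pheno_valid.all() else None
    if use_pheno is not None and set(np.unique(use_pheno)) <= {1.0, 2.0}:
        use_pheno = use_pheno - 1.0  # case/control 1/2 -> 0/1
    return GenotypePanel(samples=samples, snps=snps, dosage=dosage, pheno=use_pheno)


def write_genotypes(gp: GenotypePanel, prefix) -> None:
    """Write a panel as PLINK 1 bed/bim/fam (SNP-major)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = gp.n_ind, gp.m_snp
    snps = gp.snps
    bim = pd.DataFrame(
        {
            "chrom": snps["chrom"],
            "snp_id": snps["snp_id"],
            "cm": 0,
            "pos": snps["pos"],
            "a1": snps["a1"],
            "a2": snps["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    if gp.pheno is not None:
        ph = np.asarray(gp.pheno, float)
        if set(np.unique(ph)) <= {0.0, 1.0}:
            ph = ph + 1  # write 1/2 case-control coding
    else:
        ph = np.full(n, -9)
    fam = pd.DataFrame(
        {
            "fid": gp.samples["fid"],
            "iid": gp.samples["iid"],
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": ph,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    # inverse of _CODE_TO_DOSAGE
    d = gp.dosage.T  # (m, n)
    code = np.where(np.isnan(d), 1, np.where(d == 2, 0, np.where(d == 1, 2, 3)))
    code = code.astype(np.uint8)
    pad = (-n) % 4
    if pad:
        # pad with hom-a2 (code 3 -> dosage 0); never read back past n
        code = np.concatenate([code, np.full((m, pad), 3, np.uint8)], axis=1)
    quads = code.reshape(m, -1, 4)
    packed = (
        quads[:, :, 0]
        | (quads[:, :, 1] << 2)
        | (quads[:, :, 2] << 4)
        | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        packed.tofile(fh)


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------


def _is_ambiguous(a1: pd.Series, a2: pd.Series) -> pd.Series:
    """Strand-ambiguous (palindromic) A/T and C/G variants."""
    return a1.map(_COMPLEMENT) == a2


def harmonize(ss: SummaryStats, gp: GenotypePanel):
    """Intersect summary statistics with a genotype panel.

    Keeps SNPs present in both sources (matched on snp_id, falling back
    to chrom:pos when the id intersection is empty), flips beta_hat when
    the effect allele is the panel's non-counted allele (allowing strand
    complement for non-palindromic SNPs), drops strand-ambiguous and
    allele-mismatched variants, and returns both objects in panel order.
    """
    if len(ss) == 0 or gp.m_snp == 0:
        raise EmptyInputError("harmonize: empty input")
    gp = gp.drop_monomorphic()
    st = ss.table
    amb = _is_ambiguous(st["allele_eff"], st["allele_oth"])
    if amb.any():
        logger.info("dropping %d strand-ambiguous SNPs", int(amb.sum()))
        st = st[~amb]
    panel = gp.snps
    key_ss = st["snp_id"]
    key_gp = panel["snp_id"]
    if not set(key_ss) & set(key_gp):
        key_ss = st["chrom"].astype(str) + ":" + st["pos"].astype(str)
        key_gp = panel["chrom"].astype(str) + ":" + panel["pos"].astype(str)
    ss_by_key = st.set_index(key_ss)
    shared = key_gp[key_gp.isin(ss_by_key.index)]
    if shared.empty:
        raise EmptyInputError(
            "harmonize: no shared SNPs between summary statistics and panel"
        )
    panel_idx = shared.index.to_numpy()
    sub = ss_by_key.loc[shared.to_numpy()].reset_index(drop=True)
    pa1 = panel.loc[panel_idx, "a1"].str.upper().to_numpy()
    pa2 = panel.loc[panel_idx, "a2"].str.upper().to_numpy()
    e, o = sub["allele_eff"].to_numpy(), sub["allele_oth"].to_numpy()
    ce = np.array([_COMPLEMENT[a] for a in e])
    co = np.array([_COMPLEMENT[a] for a in o])
    same = ((e == pa1) & (o == pa2)) | ((ce == pa1) & (co == pa2))
    flip = ((e == pa2) & (o == pa1)) | ((ce == pa2) & (co == pa1))
    keep = same | flip
    if (~keep).any():
        logger.info("dropping %d allele-mismatched SNPs", int((~keep).sum()))
    sub = sub[keep].reset_index(drop=True)
    panel_idx = panel_idx[keep]
    sign = np.where(flip[keep], -1.0, 1.0)
    sub["beta"] = sub["beta"].to_numpy() * sign
    # after alignment the effect allele is the panel's counted allele
    sub["allele_eff"] = pa1[keep]
    sub["allele_oth"] = pa2[keep]
    if sub.empty:
        raise EmptyInputError("harmonize: no SNPs left after allele matching")
    return SummaryStats(sub), gp.subset(snp_idx=panel_idx)


def exclude_region(ss: SummaryStats, chrom: str, start: int, end: int) -> SummaryStats:
    """Remove SNPs inside a closed 1-based interval on one chromosome."""
    if not start < end:
        raise ValueError("region start must be < end")
    t = ss.table
    inside = (t["chrom"].astype(str) == str(chrom)) & t["pos"].between(start, end)
    out = t[~inside].reset_index(drop=True)
    if out.empty:
        warnings.warn("exclude_region removed every SNP", stacklevel=2)
    return SummaryStats(out)
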