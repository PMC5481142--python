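"""Annotation tracks and the SNP x annotation membership structure.

Continuous functionality scores (e.g. genome-wide functional-potential
tracks in [0, 1]) are smoothed over a physical window and dichotomized at
0.5; binary tracks are stacked into an M x (K+1) membership matrix whose
first column is the whole genome.  Each SNP's annotation *combination*
class (the intersection of every track it is in and the complement of
every track it is not in) drives the causal-fraction prior.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationSet",
    "smooth_scores",
    "dichotomize",
    "build_annotation_set",
    "track_from_bed",
    "track_from_table",
]


@dataclass
class AnnotationSet:
    """Binary membership of M SNPs in K annotation tracks plus the genome.

    membership column 0 is all ones (the whole genome); combo_id labels
    each SNP's annotation-combination class and combo_sizes gives the
    class sizes, which partition the SNP set.
    """

    names: list[str]  # K+1 labels, names[0] == "genome"
    membership: np.ndarray  # (M, K+1) int8
    combo_id: np.ndarray  # (M,) int, class index per SNP
    combo_sizes: np.ndarray  # (n_classes,) int

    @property
    def m_snp(self) -> int:
        return self.membership.shape[0]

    @property
    def k(self) -> int:
        return self.membership.shape[1] - 1

    @property
    def n_classes(self) -> int:
        return len(self.combo_sizes)

    def __post_init__(self) -> None:
        assert np.all(self.membership[:, 0] == 1), "column 0 must be the genome"
        assert self.combo_sizes.sum() == self.m_snp


def smooth_scores(scores, positions, window: float) -> np.ndarray:
    """Mean-smooth per-position scores over a centered bp window.

    Each output value is the mean of all input values whose position lies
    within +-window/2 bp of the target position (the value itself
    included; windows truncate at the ends of the chromosome).
    """
    scores = np.asarray(scores, float)
    positions = np.asarray(positions, float)
    if window <= 0:
        raise ValueError("window must be > 0")
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted within the chromosome")
    half = window / 2.0
    lo = np.searchsorted(positions, positions - half, side="left")
    hi = np.searchsorted(positions, positions + half, side="right")
    csum = np.concatenate([[0.0], np.cumsum(scores)])
    return (csum[hi] - csum[lo]) / (hi - lo)


def dichotomize(scores, cutoff: float = 0.5) -> np.ndarray:
    """Binary track: 1 iff score strictly exceeds the cutoff."""
    scores = np.asarray(scores, float)
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise ValueError("scores must lie in [0, 1]")
    track = (scores > cutoff).astype(np.int8)
    if scores.size and track.sum() == 0:
        warnings.warn("dichotomized track is empty (no score above cutoff)", stacklevel=2)
    return track


def build_annotation_set(
    n_snp: int,
    tracks: list[np.ndarray] | None = None,
    names: list[str] | None = None,
    min_class_size: int = 10,
) -> AnnotationSet:
    """Assemble the membership matrix and combination partition.

    Combination classes smaller than ``min_class_size`` are merged into
    their nearest superset class (the existing class whose annotation
    pattern drops the fewest tracks), keeping the causal-fraction prior's
    per-class heritability shares stable.
    """
    tracks = [] if tracks is None else [np.asarray(t).astype(np.int8) for t in tracks]
    for t in tracks:
        if t.shape != (n_snp,):
            raise ValueError("each track must be a length-M binary vector")
    k = len(tracks)
    if names is None:
        names = [f"annot{i+1}" for i in range(k)]
    if len(names) != k:
        raise ValueError("names must match the number of tracks")
    membership = np.ones((n_snp, k + 1), dtype=np.int8)
    for j, t in enumerate(tracks):
        membership[:, j + 1] = t
    # bit pattern over the K tracks identifies the combination class
    pattern = np.zeros(n_snp, dtype=np.int64)
    for j, t in enumerate(tracks):
        pattern |= t.astype(np.int64) << j
    pattern = _merge_small_classes(pattern, k, min_class_size)
    uniq, combo_id, sizes = np.unique(pattern, return_inverse=True, return_counts=True)
    return AnnotationSet(
        names=["genome"] + list(names),
        membership=membership,
        combo_id=combo_id,
        combo_sizes=sizes,
    )


def _merge_small_classes(pattern: np.ndarray, k: int, floor: int) -> np.ndarray:
    """Reassign SNPs in classes smaller than ``floor`` to a superset class."""
    if floor <= 1 or k == 0:
        return pattern
    pattern = pattern.copy()
    while True:
        uniq, counts = np.unique(pattern, return_counts=True)
        small = uniq[counts < floor]
        if small.size == 0 or uniq.size == 1:
            return pattern
        sizes = dict(zip(uniq.tolist(), counts.tolist()))
        # merge the smallest class first
        p = int(small[np.argmin([sizes[s] for s in small])])
        candidates = [
            int(q) for q in uniq if q != p and (int(q) & p) == int(q)
        ]  # q's pattern is a sub-pattern of p (drop some tracks)
        if candidates:
            # drop as few tracks as possible; break ties toward the bigger class
            target = max(candidates, key=lambda q: (bin(q).count("1"), sizes[q]))
        else:
            target = int(uniq[np.argmax(counts)])
            if target == p:  # only tiny classes remain
                target = int(uniq[0]) if uniq[0] != p else int(uniq[-1])
        logger.info(
            "merging combination class %s (%d SNPs) into %s", p, sizes[p], target
        )
        pattern[pattern == p] = target


def track_from_table(snps: pd.DataFrame, table: pd.DataFrame, value_col: str = "score"):
    """Per-SNP scores from a table keyed by snp_id (missing SNPs get 0)."""
    s = table.set_index("snp_id")[value_col]
    return snps["snp_id"].map(s).fillna(0.0).to_numpy(float)


def track_from_bed(snps: pd.DataFrame, bed: pd.DataFrame) -> np.ndarray:
    """Binary membership of SNPs in BED intervals.

    BED rows are (chrom, start, end) half-open 0-based; a SNP at 1-based
    position p is inside iff start < p <= end.
    """
    out = np.zeros(len(snps), dtype=np.int8)
    for chrom, grp in bed.groupby(bed.columns[0]):
        sel = snps["chrom"].astype(str) == str(chrom)
        if not sel.any():
            continue
        pos = snps.loc[sel, "pos"].to_numpy(np.int64)
        starts = grp.iloc[:, 1].to_numpy(np.int64)
        ends = grp.iloc[:, 2].to_numpy(np.int64)
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        inside = np.zeros(pos.size, bool)
        for s, e in zip(starts, ends):
            inside |= (pos > s) & (pos <= e)
        out[np.flatnonzero(sel)] = inside
    return out
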