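"""End-to-end run orchestration: simulate -> h2part -> prior -> infer -> score.

A ``RunConfig`` (YAML-serializable) drives the whole pipeline and is
written alongside every output; a single global seed fans out into
independent named substreams per stage, so e.g. changing the sampler
iteration count does not perturb the simulation draws.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .annotations import build_annotation_set
from .experiments import annopred_prs
from .io_formats import read_genotypes, read_sumstats, write_genotypes, write_sumstats
from .priors import DEFAULT_P0_GRID
from .simulate import SimScenario, sim_annotations, sim_panel, sim_trait, split_data, sumstats_from_panel

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

_PRIOR_VARIANTS = {"variance", "fraction"}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the global seed."""
    h = np.random.SeedSequence(
        entropy=seed, spawn_key=tuple(stage.encode())
    ).generate_state(1)[0]
    return int(h % (2**31))


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str
    seed: int = 0
    # simulation stage (used when no external data are given)
    n_ind: int = 1200
    m_snp: int = 500
    m_causal: int = 30
    h2: float = 0.5
    k_annot: int = 2
    annot_fraction: float = 0.1
    ld_rho: float = 0.5
    ld_block_len: int = 10
    # model stage
    prior_variants: tuple = ("variance", "fraction")
    p0_grid: tuple = DEFAULT_P0_GRID
    n_blocks: int = 3000
    ld_radius: float = 50
    ld_unit: str = "snp"
    ld_shrink: float = 0.0
    gibbs_iters: int = 100
    gibbs_burnin: int = 60
    top_pct: float = 5.0

    def validate(self) -> None:
        bad = set(self.prior_variants) - _PRIOR_VARIANTS
        if bad:
            raise ValueError(f"unknown prior variant(s): {sorted(bad)}")
        if not all(0 < p <= 1 for p in self.p0_grid):
            raise ValueError("p0 grid values must lie in (0, 1]")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full simulated pipeline and write artifacts to out_dir.

    Stages: simulate a cohort and annotations, write/re-read them in
    the standard formats (so I/O is exercised end to end), compute
    training summary statistics, partition heritability, build the
    priors, infer posterior effects over the tuning grid, score the
    validation cohort and evaluate.  Identical config + seed gives
    byte-identical metrics.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    scen = SimScenario(
        n_ind=config.n_ind,
        m_snp=config.m_snp,
        m_causal=config.m_causal,
        h2=config.h2,
        k_annot=config.k_annot,
        annot_fraction=config.annot_fraction,
        ld_rho=config.ld_rho,
        ld_block_len=config.ld_block_len,
        seed=config.seed,
    )
    gp = sim_panel(scen, seed=stage_seed(config.seed, "panel"))
    ann = sim_annotations(
        config.m_snp, k=config.k_annot, fraction=config.annot_fraction,
        seed=stage_seed(config.seed, "annotations"),
    )
    pheno, _ = sim_trait(gp, scen, ann, seed=np.random.default_rng(stage_seed(config.seed, "trait")))
    train, valid = split_data(gp, pheno, fractions=(0.7, 0.3), seed=stage_seed(config.seed, "split"))

    # round-trip through the on-disk formats
    write_genotypes(valid, out / "valid")
    ss = sumstats_from_panel(train, train.pheno)
    write_sumstats(ss, out / "train_sumstats.tsv")
    ss = read_sumstats(out / "train_sumstats.tsv")
    valid_rt = read_genotypes(out / "valid")
    valid_rt.pheno = valid.pheno  # continuous phenotype carried in memory

    tuned = annopred_prs(
        ss,
        valid_rt,
        ann,
        p0_grid=tuple(config.p0_grid),
        variants=tuple(config.prior_variants),
        n_blocks=config.n_blocks,
        iters=config.gibbs_iters,
        burnin=config.gibbs_burnin,
        radius=config.ld_radius,
        unit=config.ld_unit,
        seed=stage_seed(config.seed, "sampler"),
    )
    metrics = {
        "annopred": tuned["metrics"],
        "chosen": tuned["chosen"],
        "h2_total": tuned["h2_total"],
        "tau": list(np.asarray(tuned["tau"], float)),
    }
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": ["simulate", "io", "h2part", "prior", "infer", "score", "evaluate"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return metrics
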