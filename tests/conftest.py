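import numpy as np
import pandas as pd
import pytest

from annopred.io_formats import GenotypePanel, SummaryStats
from annopred.simulate import SimScenario, sim_annotations, sim_panel, sim_trait


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def tiny_panel():
    """4 individuals x 3 SNPs with one missing genotype."""
    dosage = np.array(
        [
            [0.0, 1.0, 2.0],
            [1.0, 0.0, 2.0],
            [2.0, np.nan, 1.0],
            [0.0, 1.0, 0.0],
        ]
    )
    snps = pd.DataFrame(
        {
            "snp_id": ["rs1", "rs2", "rs3"],
            "chrom": ["1", "1", "2"],
            "pos": [100, 200, 150],
            "a1": ["A", "C", "G"],
            "a2": ["G", "T", "A"],
        }
    )
    samples = pd.DataFrame({"fid": list("ABCD"), "iid": ["i1", "i2", "i3", "i4"]})
    return GenotypePanel(samples=samples, snps=snps, dosage=dosage)


@pytest.fixture
def toy_sumstats():
    t = pd.DataFrame(
        {
            "snp_id": ["rs1", "rs2", "rs3", "rs4", "rs5"],
            "chrom": ["1"] * 5,
            "pos": [100, 200, 300, 400, 500],
            "allele_eff": ["A", "C", "G", "T", "A"],
            "allele_oth": ["G", "T", "A", "G", "C"],
            "beta": [0.01, -0.02, 0.005, 0.03, -0.015],
            "n": [1000.0] * 5,
        }
    )
    return SummaryStats(t)


@pytest.fixture(scope="session")
def small_study():
    """A small simulated cohort shared by read-only tests."""
    scen = SimScenario(n_ind=600, m_snp=800, m_causal=40, h2=0.5, seed=7)
    gp = sim_panel(scen)
    ann = sim_annotations(scen.m_snp, k=2, fraction=0.1, seed=8)
    pheno, beta = sim_trait(gp, scen, ann)
    return {"scenario": scen, "panel": gp, "annotations": ann, "pheno": pheno, "beta": beta}
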