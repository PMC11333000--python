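import numpy as np
import pandas as pd
import pytest

from titr.datamodel import GenotypeMatrix, SummaryStats, p_from_chi2
from titr.simulate import SimConfig


def tiny_config(**kw) -> SimConfig:
    """A fast, small study configuration for unit tests."""
    base = dict(seed=0, n_snps=400, n_blocks=40, n_gwas=600, n_train=300,
                n_valid=200, n_panel=150, h2=0.5, n_causal=40, n_tissues=6,
                causal_tissues=("adipose", "blood"))
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def tiny_cfg() -> SimConfig:
    return tiny_config()


def make_sumstats(n: int = 20, seed: int = 0, chrom: int = 1) -> SummaryStats:
    rng = np.random.default_rng(seed)
    chi2 = rng.chisquare(1, size=n)
    return SummaryStats(pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(n)],
        "chrom": chrom,
        "pos": (np.arange(n) + 1) * 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "beta": rng.normal(0, 0.1, size=n),
        "p_value": p_from_chi2(chi2),
        "chi2": chi2,
        "n_eff": 1000.0,
        "maf": rng.uniform(0.05, 0.5, size=n),
    }))


def make_genotypes(n_samples: int = 10, n_snps: int = 5, seed: int = 0,
                   label: str = "test") -> GenotypeMatrix:
    rng = np.random.default_rng(seed)
    dosages = rng.integers(0, 3, size=(n_samples, n_snps)).astype(np.int8)
    variants = pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(n_snps)],
        "chrom": 1,
        "pos": (np.arange(n_snps) + 1) * 1000,
        "effect_allele": "A",
        "other_allele": "G",
    })
    return GenotypeMatrix([f"s{i}" for i in range(n_samples)], variants,
                          dosages, label)
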