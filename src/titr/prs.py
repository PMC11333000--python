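"""Allelic scoring, the p-value threshold grid, principal components and
the coding-region covariate score.

Scores are raw weighted allele counts, score_i = sum_j beta_j d_ij over
the SNPs surviving the p-value ceiling. Missing dosages contribute
exactly zero (no mean imputation), matching the behaviour of PLINK's
linear scoring tool with mean imputation disabled. The raw-sum scale
(rather than a per-allele average) is deliberate: the score enters
downstream regressions as a covariate, where any affine rescaling is
absorbed by the fitted coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MISSING, CovariateTable, GenotypeMatrix, SummaryStats
from .io import harmonize_stats_to_panel
from .ldops import ClumpResult, block_sample
from .datamodel import Partition

logger = logging.getLogger(__name__)


@dataclass
class PrsProfile:
    """Per-sample allelic scores with provenance."""

    sample_ids: list[str]
    score: np.ndarray
    snp_count: int
    p_threshold: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        if not np.isfinite(self.score).all():
            raise ValueError("scores must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "score": self.score,
                             "snp_count": self.snp_count})


def threshold_grid(n: int = 370, p_min: float = 1e-5, p_max: float = 1.0) -> np.ndarray:
    """Log-uniform grid of p-value ceilings, endpoints included."""
    if n < 2:
        raise ValueError("grid needs at least 2 thresholds")
    if not 0 < p_min < p_max <= 1:
        raise ValueError(f"require 0 < p_min < p_max <= 1, got ({p_min}, {p_max})")
    grid = np.geomspace(p_min, p_max, n)
    grid[0], grid[-1] = p_min, p_max
    return grid


def compute_prs(genotypes: GenotypeMatrix, stats: SummaryStats, snps: set[str],
                p_threshold: float, provenance: dict | None = None) -> PrsProfile:
    """Weighted allele-count score over a SNP set at a p-value ceiling.

    Alleles are harmonized to the genotype panel (sign flips for swapped
    alleles; ambiguous and mismatched SNPs dropped); SNPs absent from the
    genotypes are dropped with a logged count; missing dosages count 0.
    """
    aligned = harmonize_stats_to_panel(stats.subset(snps), genotypes)
    absent = len(set(snps) & set(stats.snp_ids)) - len(aligned)
    if absent > 0:
        logger.info("compute_prs: %d SNPs dropped during harmonization", absent)
    t = aligned.table
    t = t[t["p_value"] <= p_threshold]
    if t.empty:
        return PrsProfile(list(genotypes.sample_ids),
                          np.zeros(genotypes.n_samples), 0, p_threshold,
                          provenance or {})
    sub = genotypes.subset_snps(t["snp_id"].tolist())
    d = sub.dosages.astype(float)
    d[sub.dosages == MISSING] = 0.0
    score = d @ t["beta"].to_numpy(dtype=float)
    return PrsProfile(list(genotypes.sample_ids), score, len(t), p_threshold,
                      provenance or {})


def compute_pcs(genotypes: GenotypeMatrix, k: int = 10) -> np.ndarray:
    """Top-k principal components of the standardized dosage matrix.

    Missing dosages are mean-imputed for the PCA only. Component signs
    follow a fixed convention (largest-magnitude loading positive), so
    repeated runs are identical.
    """
    n, m = genotypes.n_samples, genotypes.n_snps
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} samples, have {n}")
    if k >= min(n, m):
        raise ValueError(f"k={k} must be below min(samples, SNPs)={min(n, m)}")
    x = genotypes.dosage_float()
    mean = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(mean, inds[1])
    sd = x.std(axis=0)
    xs = (x - x.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    if min(n, m) <= 600:
        u, s, vt = np.linalg.svd(xs, full_matrices=False)
    else:
        # seeded randomized range finder with power iterations: exact
        # enough for leading components at a fraction of the cost
        rng = np.random.default_rng(1905)
        y = xs @ rng.standard_normal((m, k + 10))
        for _ in range(4):
            y, _ = np.linalg.qr(xs @ (xs.T @ y))
        q, _ = np.linalg.qr(y)
        ub, s, vt = np.linalg.svd(q.T @ xs, full_matrices=False)
        u = q @ ub
    pcs = u[:, :k] * s[:k]
    for i in range(k):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            pcs[:, i] = -pcs[:, i]
    return pcs


def pc_covariates(genotypes: GenotypeMatrix, age: np.ndarray, sex: np.ndarray,
                  k: int = 10) -> CovariateTable:
    """Assemble the standard covariate table with fresh PCs."""
    pcs = compute_pcs(genotypes, k=k)
    frame = pd.DataFrame({"age": age, "sex": sex},
                         index=pd.Index(genotypes.sample_ids, name="sample_id"))
    for i in range(k):
        frame[f"pc{i + 1}"] = pcs[:, i]
    return CovariateTable(frame)


def build_coding_covariate(
    stats: SummaryStats,
    clumps: ClumpResult,
    train_genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    covariates: CovariateTable,
    coding_snps: set[str],
    other_genotypes: GenotypeMatrix | None = None,
    grid: np.ndarray | None = None,
) -> tuple[PrsProfile, PrsProfile | None, float]:
    """Independently-optimized coding-region score used as a model covariate.

    A standard pruning-and-thresholding model restricted to the coding
    SNP mask: one representative per LD block, then the threshold-grid
    value maximizing adjusted-R2 gain over the age/sex/PC covariates in
    the training cohort. The chosen threshold is applied unchanged to the
    second cohort when given.
    """
    from .select import delta_r2, fit_model  # local import to avoid a cycle

    if grid is None:
        grid = threshold_grid()
    if not coding_snps:
        logger.warning("build_coding_covariate: empty coding SNP set; zero profile")
        zero = PrsProfile(list(train_genotypes.sample_ids),
                          np.zeros(train_genotypes.n_samples), 0, 1.0,
                          {"model": "coding"})
        other = None
        if other_genotypes is not None:
            other = PrsProfile(list(other_genotypes.sample_ids),
                               np.zeros(other_genotypes.n_samples), 0, 1.0,
                               {"model": "coding"})
        return zero, other, 1.0

    partition = Partition("coding", ("top", 1.0), frozenset(coding_snps))
    selected = block_sample(clumps, partition, set())
    cov_design = covariates.design_columns(include_coding=False)
    null = fit_model(phenotype, cov_design)
    best = (-np.inf, float(grid[-1]))
    for thr in grid:
        profile = compute_prs(train_genotypes, stats, selected, float(thr))
        if profile.snp_count == 0:
            continue
        full = fit_model(phenotype, cov_design, {"coding_prs": profile.score})
        gain = delta_r2(full, null)
        if gain > best[0]:
            best = (gain, float(thr))
    thr = best[1]
    train_profile = compute_prs(train_genotypes, stats, selected, thr,
                                {"model": "coding", "threshold": thr})
    other_profile = None
    if other_genotypes is not None:
        other_profile = compute_prs(other_genotypes, stats, selected, thr,
                                    {"model": "coding", "threshold": thr})
    return train_profile, other_profile, thr
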