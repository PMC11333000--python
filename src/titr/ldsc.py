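"""Stratified LD-score regression for partitioned SNP heritability.

The per-SNP expectation under the polygenic model is

    E[chi2_j] = 1 + N * sum_C tau_C * ell(j, C)

where ell(j, C) = sum_k a_C(k) r2(j, k) is the annotation-stratified LD
score of SNP j over a physical window. A weighted least-squares fit of
chi2 on {N * ell(., C)} with a free intercept yields the per-annotation
coefficients tau_C; standard errors come from a delete-one block
jackknife over contiguous SNP blocks. The standardized effect

    tau*_C = tau_C * sd(a_C) * M / h2_total

is the proportional change in per-SNP heritability per one standard
deviation of annotation value, and is the tissue-prioritization statistic
used throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import GenotypeMatrix, SummaryStats

logger = logging.getLogger(__name__)

BASELINE = "base"


class CollinearityError(ValueError):
    """Annotation design is singular; names the offending columns."""


@dataclass
class LdScoreTable:
    """Annotation-stratified LD scores, row-aligned with an annotation matrix.

    The first annotation column is the all-ones baseline.
    """

    snp_ids: np.ndarray
    annotation_names: list[str]
    annotations: np.ndarray  # M x C
    ell: np.ndarray  # M x C
    window_kb: float
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids)
        self.annotations = np.asarray(self.annotations, dtype=float)
        self.ell = np.asarray(self.ell, dtype=float)
        m = len(self.snp_ids)
        c = len(self.annotation_names)
        if self.annotations.shape != (m, c) or self.ell.shape != (m, c):
            raise ValueError("annotation/ell shapes inconsistent with names")

    def columns(self, names: list[str]) -> "LdScoreTable":
        idx = [self.annotation_names.index(n) for n in names]
        return LdScoreTable(self.snp_ids, list(names), self.annotations[:, idx],
                            self.ell[:, idx], self.window_kb, self.chrom, self.pos)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"snp_id": self.snp_ids})
        for i, name in enumerate(self.annotation_names):
            df[f"L2_{name}"] = self.ell[:, i]
        return df


@dataclass
class SldscFit:
    """Per-annotation stratified regression results."""

    annotation_names: list[str]
    tau: np.ndarray
    tau_se: np.ndarray
    tau_star: np.ndarray
    tau_star_se: np.ndarray
    tau_star_p: np.ndarray
    enrichment: np.ndarray
    enrichment_se: np.ndarray
    prop_h2: np.ndarray
    h2_total: float
    intercept: float
    n_blocks: int
    n_snps: int
    annotations: np.ndarray = field(repr=False, default=None)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "annotation": self.annotation_names,
            "tau": self.tau, "tau_se": self.tau_se,
            "tau_star": self.tau_star, "tau_star_se": self.tau_star_se,
            "tau_star_p": self.tau_star_p,
            "enrichment": self.enrichment, "enrichment_se": self.enrichment_se,
            "prop_h2": self.prop_h2,
        })

    def get(self, name: str, fld: str) -> float:
        i = self.annotation_names.index(name)
        return float(getattr(self, fld)[i])


# ---------------------------------------------------------------------------
# LD scores


def compute_ld_scores(panel: GenotypeMatrix, annotations: np.ndarray,
                      annotation_names: list[str] | None = None,
                      window_kb: float = 1000.0) -> LdScoreTable:
    """Annotation-stratified LD scores from a reference dosage panel.

    r2(j, k) is the squared Pearson correlation of dosages
    (pairwise-complete over non-missing samples); ell(j, C) sums
    a_C(k) * r2(j, k) over SNPs k within window_kb of j on the same
    chromosome, including j itself. Monomorphic SNPs contribute r2 = 0.
    """
    if panel.n_samples < 2:
        raise ValueError("panel needs at least 2 samples")
    annotations = np.atleast_2d(np.asarray(annotations, dtype=float))
    if annotations.shape[0] != panel.n_snps:
        annotations = annotations.T
    if annotations.shape[0] != panel.n_snps:
        raise ValueError("annotation matrix not row-aligned with panel SNPs")
    c = annotations.shape[1]
    if annotation_names is None:
        annotation_names = [BASELINE] + [f"annot_{i}" for i in range(1, c)]

    x = panel.dosage_float()
    has_missing = np.isnan(x).any()
    mean = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0)
    mono = sd == 0
    if mono.any():
        logger.info("compute_ld_scores: %d monomorphic SNPs contribute r2=0",
                    int(mono.sum()))
    sd_safe = np.where(mono, np.inf, sd)
    xs = (x - mean) / sd_safe
    if has_missing:
        obs = np.isfinite(xs)
        xs = np.nan_to_num(xs)
    n = panel.n_samples

    chrom = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy(dtype=float)
    window_bp = window_kb * 1000.0
    m = panel.n_snps
    ell = np.zeros((m, c))
    order = np.lexsort((pos, chrom))
    for j_idx, j in enumerate(order):
        lo = j_idx
        while lo > 0 and chrom[order[lo - 1]] == chrom[j] and \
                pos[j] - pos[order[lo - 1]] <= window_bp:
            lo -= 1
        hi = j_idx
        while hi + 1 < m and chrom[order[hi + 1]] == chrom[j] and \
                pos[order[hi + 1]] - pos[j] <= window_bp:
            hi += 1
        k = order[lo:hi + 1]
        if mono[j]:
            r2 = np.zeros(len(k))
            self_pos = np.where(k == j)[0]
            r2[self_pos] = 0.0
        elif has_missing:
            r2 = _pairwise_r2_masked(xs, obs, j, k)
        else:
            r = xs[:, j] @ xs[:, k] / n
            r2 = r * r
            r2[mono[k]] = 0.0
        ell[j] = r2 @ annotations[k]
    return LdScoreTable(panel.snp_ids, annotation_names, annotations, ell,
                        window_kb, chrom=chrom, pos=pos.astype(int))


def _pairwise_r2_masked(xs: np.ndarray, obs: np.ndarray, j: int,
                        k: np.ndarray) -> np.ndarray:
    """Pairwise-complete squared correlations of SNP j with SNPs k."""
    out = np.zeros(len(k))
    xj = xs[:, j]
    oj = obs[:, j]
    for i, kk in enumerate(k):
        both = oj & obs[:, kk]
        nb = both.sum()
        if nb < 2:
            continue
        a = xs[both, j]
        b = xs[both, kk]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            continue
        r = ((a - a.mean()) * (b - b.mean())).mean() / (sa * sb)
        out[i] = r * r
    return out


# ---------------------------------------------------------------------------
# stratified regression


def _check_collinear(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = []
        kept: list[int] = []
        for i in range(design.shape[1]):
            cand = design[:, kept + [i]]
            if np.linalg.matrix_rank(cand) == len(kept) + 1:
                kept.append(i)
            else:
                bad.append(names[i])
        raise CollinearityError(f"collinear annotation columns: {bad}")


def fit_sldsc(stats: SummaryStats, lds: LdScoreTable, n_blocks: int = 200) -> SldscFit:
    """Stratified LD-score regression with block-jackknife uncertainty.

    Two-step heteroskedasticity weighting: an initial unweighted pass
    predicts per-SNP chi2, then the final weighted least squares uses
    weights 1 / (max(ell_base, 1) * pred^2). tau standard errors, tau*,
    enrichment and their SEs all come from a delete-one jackknife over
    n_blocks contiguous SNP blocks (reduced to floor(M/50) for small M).
    """
    t = stats.table.set_index("snp_id")
    idx = pd.Index(lds.snp_ids)
    shared = idx.intersection(t.index)
    if len(shared) < 200:
        raise ValueError(f"stats and LD scores share only {len(shared)} SNPs (< 200)")
    keep = idx.get_indexer(shared)
    # deterministic genomic order for jackknife blocks
    if lds.chrom is not None and lds.pos is not None:
        order = np.lexsort((lds.snp_ids[keep], lds.pos[keep], lds.chrom[keep]))
    else:
        order = np.argsort(lds.snp_ids[keep])
    keep = keep[order]
    snp_order = lds.snp_ids[keep]
    ell = lds.ell[keep]
    annot = lds.annotations[keep]
    sub = t.loc[snp_order]
    chi2 = sub["chi2"].to_numpy(dtype=float)
    n_eff = sub["n_eff"].to_numpy(dtype=float)
    if not np.isfinite(n_eff).all():
        raise ValueError("n_eff missing for some SNPs; heritability dialect required")
    m = len(chi2)

    if n_blocks > m // 50:
        reduced = max(2, m // 50)
        logger.info("fit_sldsc: reducing n_blocks from %d to %d for M=%d",
                    n_blocks, reduced, m)
        n_blocks = reduced

    x = np.column_stack([np.ones(m), n_eff[:, None] * ell])
    names = ["intercept"] + list(lds.annotation_names)
    _check_collinear(x, names)

    # step 1: unweighted pass -> predicted chi2 for variance weights
    theta0, *_ = np.linalg.lstsq(x, chi2, rcond=None)
    pred = np.maximum(x @ theta0, 1e-3)
    ell_base = ell[:, 0] if lds.annotation_names[0] == BASELINE else np.ones(m)
    w = 1.0 / (np.maximum(ell_base, 1.0) * pred ** 2)

    xw = x * w[:, None]
    xtwx = x.T @ xw
    xtwy = xw.T @ chi2

    bounds = np.linspace(0, m, n_blocks + 1).astype(int)
    block_xtwx = np.empty((n_blocks, x.shape[1], x.shape[1]))
    block_xtwy = np.empty((n_blocks, x.shape[1]))
    for b in range(n_blocks):
        sl = slice(bounds[b], bounds[b + 1])
        xb = x[sl]
        xwb = xw[sl]
        block_xtwx[b] = xb.T @ xwb
        block_xtwy[b] = xwb.T @ chi2[sl]

    theta = np.linalg.solve(xtwx, xtwy)

    sums = annot.sum(axis=0)
    sds = annot.std(axis=0)

    def derived(th: np.ndarray) -> dict[str, np.ndarray | float]:
        tau = th[1:]
        h2 = float(tau @ sums)
        with np.errstate(divide="ignore", invalid="ignore"):
            tau_star = np.where(tau == 0, 0.0, tau * sds * m / h2 if h2 != 0 else np.nan)
        per_snp_h2 = annot @ tau
        member = annot != 0
        prop = np.array([per_snp_h2[member[:, c]].sum() for c in range(annot.shape[1])])
        prop = prop / h2 if h2 != 0 else np.full(annot.shape[1], np.nan)
        prop_snps = member.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            enr = np.where(prop_snps > 0, prop / prop_snps, np.nan)
        return {"tau": tau, "h2": h2, "tau_star": tau_star, "prop": prop, "enr": enr}

    full = derived(theta)

    reps = {key: [] for key in ("tau", "tau_star", "prop", "enr")}
    for b in range(n_blocks):
        th_b = np.linalg.solve(xtwx - block_xtwx[b], xtwy - block_xtwy[b])
        d = derived(th_b)
        for key in reps:
            reps[key].append(d[key])

    def jack_se(values: list[np.ndarray]) -> np.ndarray:
        arr = np.asarray(values, dtype=float)
        g = arr.shape[0]
        mean = np.nanmean(arr, axis=0)
        return np.sqrt((g - 1) / g * np.nansum((arr - mean) ** 2, axis=0))

    tau_se = jack_se(reps["tau"])
    enrichment_se = jack_se(reps["enr"])
    # tau* inference follows the reference convention: the standardizing
    # factor sd(a) * M / h2 is treated as a plug-in constant, so the tau*
    # z-score equals the tau z-score
    h2 = full["h2"]
    scale = np.abs(sds * m / h2) if h2 != 0 else np.full_like(sds, np.nan)
    tau_star_se = tau_se * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(full["tau"] == 0, 0.0, full["tau"] / tau_se)
    tau_star_p = 2 * sps.norm.sf(np.abs(z))

    return SldscFit(
        annotation_names=list(lds.annotation_names),
        tau=full["tau"], tau_se=tau_se,
        tau_star=full["tau_star"], tau_star_se=tau_star_se, tau_star_p=tau_star_p,
        enrichment=full["enr"], enrichment_se=enrichment_se,
        prop_h2=full["prop"], h2_total=full["h2"], intercept=float(theta[0]),
        n_blocks=n_blocks, n_snps=m, annotations=annot,
    )


def proportion_h2(fit: SldscFit, partition_annotation: str) -> float:
    """Fraction of total heritability carried by a fitted partition annotation.

    Per-SNP heritability is sum_C tau_C a_C(j); membership in the
    partition is a nonzero annotation value.
    """
    if fit.h2_total <= 0:
        raise ValueError("h2_total <= 0; proportion undefined")
    i = fit.annotation_names.index(partition_annotation)
    member = fit.annotations[:, i] != 0
    per_snp = fit.annotations @ fit.tau
    return float(per_snp[member].sum() / fit.h2_total)


def select_candidates(fits: dict[str, SldscFit], n_tissues: int = 51,
                      alpha: float = 0.05) -> list[str]:
    """Bonferroni tissue gate: tau* > 0 and p < alpha / n_tissues.

    ``fits`` maps tissue label to a stratified fit whose focal annotation
    is named after the tissue. Returns tissues ordered by descending
    tau*; an empty list is allowed.
    """
    threshold = alpha / n_tissues
    passed = []
    for tissue, fit in fits.items():
        ts = fit.get(tissue, "tau_star")
        p = fit.get(tissue, "tau_star_p")
        if ts > 0 and p < threshold:
            passed.append((tissue, ts))
    passed.sort(key=lambda x: -x[1])
    return [t for t, _ in passed]
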