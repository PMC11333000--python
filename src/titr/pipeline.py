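"""Orchestration: single-tissue prioritization models, the iterative
tissue-refinement (TITR) loop, and target-population validation.

The loop alternates four stages. (1) Partition heritability: one
stratified LD-score regression per tissue, with that tissue's
quantile-normalized score as the focal annotation; tissues pass the gate
tau* > 0 and p < 0.05 / n_tissues. (2) Calculate scores: each candidate
tissue offers its highest not-yet-consumed 0.1% percentile bin; block
sampling draws at most one new SNP per LD block given the current model.
(3) Optimize: every candidate (tissue x p-value-threshold) model of the
merged SNP set is tested against the current model — ANOVA for the
nested first iteration, the Davidson-MacKinnon J test afterwards — and
among the significant candidates the one with the greatest adjusted-R2
gain wins; only the winner's bin cursor advances. (4) Repeat until no
candidate adds significant information or the iteration cap is reached.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import TOP_FRACTIONS, bin_partition, quantile_normalize, assign_bins, \
    top_fraction_partition
from .datamodel import (AnnotationTrack, CovariateTable, GenotypeMatrix, Partition,
                        SummaryStats, TitrLog, TitrLogEntry)
from .ldops import ClumpResult, block_sample, clump
from .ldsc import SldscFit, compute_ld_scores, fit_sldsc, select_candidates
from .prs import compute_prs, threshold_grid
from .select import delta_r2, fit_model

logger = logging.getLogger(__name__)


@dataclass
class TitrConfig:
    """Tunables of the iterative loop and its supporting steps."""

    alpha: float = 0.05
    max_iterations: int = 200
    bin_resolution: float = 0.001
    clump_r2: float = 0.2
    clump_window_kb: float = 250.0
    # matched to the simulated LD decay length; widen for panels with
    # longer-range LD
    ldsc_window_kb: float = 50.0
    n_jackknife_blocks: int = 200
    n_thresholds: int = 370
    p_min: float = 1e-5
    p_max: float = 1.0

    def grid(self) -> np.ndarray:
        return threshold_grid(self.n_thresholds, self.p_min, self.p_max)


@dataclass
class TitrState:
    """Cumulative model of the iterative loop."""

    model_snps: set[str] = field(default_factory=set)
    cursors: dict[str, int] = field(default_factory=dict)
    log: TitrLog = field(default_factory=TitrLog)
    candidates: list[str] = field(default_factory=list)
    fits: dict[str, SldscFit] = field(default_factory=dict)
    status: str = "running"
    clumps: ClumpResult | None = None

    @property
    def n_iterations(self) -> int:
        return len(self.log)

    def thresholds(self) -> list[float]:
        return [e.p_threshold for e in self.log.entries]


@dataclass
class SingleTissueReport:
    """Best (fraction, threshold) single-annotation model, by training gain."""

    mode: str
    tissue: str | None
    fraction: float | None
    p_threshold: float
    delta_r2_train: float
    snp_ids: set[str]
    per_fraction: dict[float, float] = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


# ---------------------------------------------------------------------------
# fast residualized grid evaluation


class _GridScorer:
    """Adjusted-R2 gains and selection tests for many candidate scores.

    All candidate models share the design [intercept, covariates]; the
    current model adds the accepted PRS column. Projections onto the two
    orthonormal bases turn each per-threshold fit into O(n) work.
    """

    def __init__(self, phenotype: np.ndarray, covariates: pd.DataFrame,
                 current_prs: np.ndarray | None):
        self.y = np.asarray(phenotype, dtype=float)
        n = len(self.y)
        base = np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])
        self.p_base = base.shape[1] - 1
        self.q_base, _ = np.linalg.qr(base)
        cur = base if current_prs is None else np.column_stack([base, current_prs])
        self.p_cur = cur.shape[1] - 1
        self.q_cur, _ = np.linalg.qr(cur)
        self.n = n
        self.tss = float(np.sum((self.y - self.y.mean()) ** 2))
        self.y_res_base = self.y - self.q_base @ (self.q_base.T @ self.y)
        self.y_res_cur = self.y - self.q_cur @ (self.q_cur.T @ self.y)
        self.rss_base = float(self.y_res_base @ self.y_res_base)
        self.rss_cur = float(self.y_res_cur @ self.y_res_cur)
        self.adj_base = self._adj(self.rss_base, self.p_base)
        self.adj_cur = self._adj(self.rss_cur, self.p_cur)

    def _adj(self, rss: float, p: int) -> float:
        r2 = 1.0 - rss / self.tss if self.tss > 0 else 0.0
        return 1.0 - (1.0 - r2) * (self.n - 1) / (self.n - p - 1)

    def candidate(self, score: np.ndarray) -> tuple[float, np.ndarray, float]:
        """(adjusted R2 of base+score, fitted values, rss) of the candidate."""
        c = score - self.q_base @ (self.q_base.T @ score)
        nc = np.linalg.norm(c)
        if nc < 1e-10:
            fitted = self.y - self.y_res_base
            return self.adj_base, fitted, self.rss_base
        c = c / nc
        coef = c @ self.y
        rss = self.rss_base - coef ** 2
        fitted = (self.y - self.y_res_base) + coef * c
        return self._adj(rss, self.p_base + 1), fitted, rss

    def anova_p(self, rss_candidate: float) -> float:
        """F test of the candidate against the covariate-only null."""
        from scipy import stats as sps
        df1 = self.n - (self.p_base + 1) - 1
        num = max(self.rss_base - rss_candidate, 0.0)
        den = rss_candidate / df1
        if den == 0:
            return 0.0 if num > 0 else 1.0
        return float(sps.f.sf(num / den, 1, df1))

    def jtest_p(self, fitted: np.ndarray) -> float:
        """J test of the candidate's fitted values against the current model."""
        from scipy import stats as sps
        f_res = fitted - self.q_cur @ (self.q_cur.T @ fitted)
        nf = np.linalg.norm(f_res)
        if nf < 1e-8 * max(np.linalg.norm(fitted), 1e-30):
            return 1.0
        f_res = f_res / nf
        coef = f_res @ self.y
        rss = self.rss_cur - coef ** 2
        df = self.n - (self.p_cur + 1) - 1
        if rss <= 0:
            return 0.0
        t = coef / np.sqrt(rss / df)
        return float(2 * sps.t.sf(abs(t), df))


def _score_over_grid(genotypes: GenotypeMatrix, stats: SummaryStats,
                     snps: set[str], grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores for every grid threshold via a single sorted cumulative pass.

    Returns (scores [n_samples x n_thresholds], snp_counts).
    """
    from .io import harmonize_stats_to_panel
    from .datamodel import MISSING

    n = genotypes.n_samples
    aligned = harmonize_stats_to_panel(stats.subset(snps), genotypes)
    t = aligned.table.sort_values(["p_value", "snp_id"], kind="mergesort")
    if t.empty:
        return np.zeros((n, len(grid))), np.zeros(len(grid), dtype=int)
    sub = genotypes.subset_snps(t["snp_id"].tolist())
    d = sub.dosages.astype(float)
    d[sub.dosages == MISSING] = 0.0
    contrib = d * t["beta"].to_numpy(dtype=float)[None, :]
    cum = np.cumsum(contrib, axis=1)
    pvals = t["p_value"].to_numpy(dtype=float)
    counts = np.searchsorted(pvals, grid, side="right")
    scores = np.zeros((n, len(grid)))
    nonzero = counts > 0
    scores[:, nonzero] = cum[:, counts[nonzero] - 1]
    return scores, counts


# ---------------------------------------------------------------------------
# single-tissue models


def run_single_tissue(stats: SummaryStats, clumps: ClumpResult,
                      train_genotypes: GenotypeMatrix, phenotype: np.ndarray,
                      covariates: CovariateTable, mode: str = "standard",
                      track: AnnotationTrack | None = None,
                      fractions: tuple[float, ...] = TOP_FRACTIONS,
                      config: TitrConfig | None = None) -> SingleTissueReport:
    """Pruning-and-thresholding over annotation top-fraction partitions.

    ``standard`` mode uses all GWAS SNPs (the baseline model); any other
    mode requires a normalized annotation track (a tissue model or an
    organism-wide track) and searches the top 1/5/10/20/50% partitions.
    The report carries the (fraction, threshold) pair with the largest
    training-cohort adjusted-R2 gain over the covariate-only null.
    """
    config = config or TitrConfig()
    grid = config.grid()
    scorer = _GridScorer(phenotype, covariates.design_columns(), None)
    universe = frozenset(clumps.pvals)

    if mode == "standard":
        partitions = [(None, Partition("all", ("top", 1.0), universe))]
    else:
        if track is None:
            raise ValueError(f"mode {mode!r} requires an annotation track")
        partitions = [(f, top_fraction_partition(track, f)) for f in fractions]

    best = None
    per_fraction: dict[float, float] = {}
    for frac, part in partitions:
        selected = block_sample(clumps, part, set())
        scores, counts = _score_over_grid(train_genotypes, stats, selected, grid)
        frac_best = -np.inf
        for gi, thr in enumerate(grid):
            if counts[gi] == 0:
                continue
            adj, _, _ = scorer.candidate(scores[:, gi])
            gain = adj - scorer.adj_base
            if gain > frac_best:
                frac_best = gain
            if best is None or gain > best[0]:
                best = (gain, frac, float(thr), selected)
        if frac is not None:
            per_fraction[frac] = frac_best
    if best is None:
        return SingleTissueReport(mode, getattr(track, "tissue_label", None),
                                  None, 1.0, 0.0, set(), per_fraction)
    gain, frac, thr, selected = best
    return SingleTissueReport(mode, getattr(track, "tissue_label", None),
                              frac, thr, gain, selected, per_fraction)


def evaluate_prs_model(snp_ids: set[str], p_threshold: float, stats: SummaryStats,
                       genotypes: GenotypeMatrix, phenotype: np.ndarray,
                       covariates: CovariateTable) -> float:
    """Adjusted-R2 gain of a fixed SNP-set model in a given cohort."""
    profile = compute_prs(genotypes, stats, snp_ids, p_threshold)
    null = fit_model(phenotype, covariates.design_columns())
    if profile.snp_count == 0 or np.std(profile.score) == 0:
        return 0.0
    full = fit_model(phenotype, covariates.design_columns(),
                     {"prs": profile.score})
    return delta_r2(full, null)


# ---------------------------------------------------------------------------
# the iterative loop


def fit_tissue_sldsc(stats: SummaryStats, panel: GenotypeMatrix,
                     tracks: list[AnnotationTrack],
                     baseline_annotations: pd.DataFrame | None = None,
                     config: TitrConfig | None = None) -> dict[str, SldscFit]:
    """One stratified fit per tissue, conditioning on shared baselines.

    The LD scores for every annotation column are computed in a single
    pass over the panel; each tissue's fit then uses the columns
    [baseline(s), tissue focal annotation].
    """
    config = config or TitrConfig()
    tracks = quantile_normalize(tracks)
    names = ["base"]
    cols = [np.ones(panel.n_snps)]
    track_ids = tracks[0].snp_ids
    order = pd.Index(track_ids).get_indexer(panel.snp_ids)
    if (order < 0).any():
        raise ValueError("annotation tracks do not cover the panel SNPs")
    if baseline_annotations is not None:
        for c in baseline_annotations.columns:
            names.append(str(c))
            cols.append(baseline_annotations[c].to_numpy(dtype=float)[order])
    for t in tracks:
        names.append(t.tissue_label)
        cols.append(t.norm_score[order])
    lds = compute_ld_scores(panel, np.column_stack(cols), names,
                            window_kb=config.ldsc_window_kb)
    shared = ["base"] + ([str(c) for c in baseline_annotations.columns]
                         if baseline_annotations is not None else [])
    fits = {}
    for t in tracks:
        sub = lds.columns(shared + [t.tissue_label])
        fits[t.tissue_label] = fit_sldsc(stats, sub,
                                         n_blocks=config.n_jackknife_blocks)
    return fits


def run_titr(stats: SummaryStats, panel: GenotypeMatrix,
             train_genotypes: GenotypeMatrix, phenotype: np.ndarray,
             covariates: CovariateTable, tracks: list[AnnotationTrack],
             baseline_annotations: pd.DataFrame | None = None,
             config: TitrConfig | None = None,
             clumps: ClumpResult | None = None,
             fits: dict[str, SldscFit] | None = None) -> TitrState:
    """Iteratively grow a multi-tissue functional PRS in the training cohort."""
    config = config or TitrConfig()
    grid = config.grid()
    tracks = [assign_bins(t, config.bin_resolution)
              for t in quantile_normalize(tracks)]
    by_tissue = {t.tissue_label: t for t in tracks}

    state = TitrState()
    state.fits = fits if fits is not None else fit_tissue_sldsc(
        stats, panel, tracks, baseline_annotations, config)
    state.candidates = select_candidates(state.fits, n_tissues=len(tracks),
                                         alpha=config.alpha)
    if not state.candidates:
        state.status = "no_tissue_enriched"
        return state
    state.clumps = clumps if clumps is not None else clump(
        stats, panel, r2_threshold=config.clump_r2,
        window_kb=config.clump_window_kb)
    state.cursors = {t: 1 for t in state.candidates}
    n_bins = tracks[0].n_bins

    cov_design = covariates.design_columns()
    current_prs: np.ndarray | None = None

    for iteration in range(1, config.max_iterations + 1):
        scorer = _GridScorer(phenotype, cov_design, current_prs)
        adj_current = scorer.adj_base if current_prs is None else scorer.adj_cur

        proposals = []  # (gain, tissue, bin, thr_idx, new_snps, fitted, rss)
        for tissue in state.candidates:
            new_snps: set[str] = set()
            while state.cursors[tissue] <= n_bins:
                part = bin_partition(by_tissue[tissue], state.cursors[tissue])
                new_snps = block_sample(state.clumps, part, state.model_snps)
                if new_snps:
                    break
                state.cursors[tissue] += 1  # empty bins stay empty as the model grows
            if not new_snps:
                continue
            merged = state.model_snps | new_snps
            scores, counts = _score_over_grid(train_genotypes, stats, merged, grid)
            for gi, thr in enumerate(grid):
                if counts[gi] == 0:
                    continue
                adj, fitted, rss = scorer.candidate(scores[:, gi])
                gain = adj - adj_current
                if gain <= 0:
                    continue
                if iteration == 1:
                    p = scorer.anova_p(rss)
                else:
                    p = scorer.jtest_p(fitted)
                if p < config.alpha:
                    proposals.append((gain, tissue, state.cursors[tissue],
                                      float(thr), new_snps, scores[:, gi], p))
        if not proposals:
            state.status = ("no_candidate_tissue" if iteration == 1 and not any(
                state.cursors[t] <= n_bins for t in state.candidates)
                else "no_significant_addition")
            break

        proposals.sort(key=lambda x: (-x[0], x[1], x[3]))
        gain, tissue, bin_no, thr, new_snps, winner_score, p = proposals[0]
        state.model_snps |= new_snps
        state.cursors[tissue] = bin_no + 1
        current_prs = winner_score
        state.log.append(TitrLogEntry(
            iteration=iteration, tissue=tissue, bin=bin_no, p_threshold=thr,
            n_added=len(new_snps), n_cumulative=len(state.model_snps),
            delta_r2_train=gain, selection_p=p,
            snps_added=tuple(sorted(new_snps)),
        ))
    else:
        state.status = "max_iterations"
    if state.status == "running":
        state.status = "terminated"
    return state


def validate_titr(state: TitrState, stats: SummaryStats,
                  target_genotypes: GenotypeMatrix, phenotype: np.ndarray,
                  covariates: CovariateTable) -> TitrState:
    """Score each iteration's cumulative model in the target cohort.

    Fills ``delta_r2_valid`` on every log entry: the cumulative SNP set
    at iteration i, thresholded at iteration i's p ceiling, added to the
    covariate-only null in the target population.
    """
    null = fit_model(phenotype, covariates.design_columns())
    cumulative: set[str] = set()
    for entry in state.log.entries:
        cumulative |= set(entry.snps_added)
        profile = compute_prs(target_genotypes, stats, cumulative,
                              entry.p_threshold)
        if profile.snp_count == 0 or np.std(profile.score) == 0:
            entry.delta_r2_valid = 0.0
            continue
        full = fit_model(phenotype, covariates.design_columns(),
                         {"prs": profile.score})
        entry.delta_r2_valid = delta_r2(full, null)
    return state


def snp_overlap(model_a: set[str], model_b: set[str]) -> float:
    """|A intersection B| / |A|; zero (with a warning) for empty A."""
    if not model_a:
        warnings.warn("snp_overlap: empty reference set; returning 0.0")
        return 0.0
    return len(set(model_a) & set(model_b)) / len(model_a)


def validation_trace(state: TitrState) -> pd.DataFrame:
    """Per-iteration accuracy/tissue trace (the workflow's validation plot)."""
    return state.log.to_frame()


def plot_validation_trace(state: TitrState, path: str) -> None:
    """Write the iteration-vs-accuracy trace with tissue composition."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = validation_trace(state)
    fig, ax = plt.subplots(figsize=(7, 4))
    if not frame.empty:
        ax.plot(frame["iteration"], frame["delta_r2_train"].cumsum(),
                label="train (cumulative gain)")
        if frame["delta_r2_valid"].notna().any():
            ax.plot(frame["iteration"], frame["delta_r2_valid"],
                    label="target validation")
        tissues = frame["tissue"].value_counts(normalize=True)
        top = ", ".join(f"{t} {p:.0%}" for t, p in tissues.head(3).items())
        ax.set_title(f"tissue composition: {top}")
    ax.set_xlabel("iteration")
    ax.set_ylabel(r"$\Delta R^2$")
    if ax.get_legend_handles_labels()[0]:
        ax.legend(loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
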