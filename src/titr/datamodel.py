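"""Core domain types shared across the package.

The central objects are GWAS summary statistics (two tab-delimited dialects:
a heritability-partitioning view carrying per-SNP chi-square and effective
sample size, and a scoring view carrying effect sizes and p-values),
genotype dosage matrices for reference panels and cohorts, per-SNP
regulatory annotation tracks for tissue models, per-sample covariates, SNP
partitions of annotation distributions, and the iteration log of the
iterative tissue-refinement optimizer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Sentinel for a missing dosage; distinct from the valid calls {0, 1, 2}.
MISSING = np.int8(-9)

VALID_ALLELES = frozenset("ACGT")

#: Strand-ambiguous allele pairs (indistinguishable after strand flip).
AMBIGUOUS_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

SUMSTATS_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "p_value",
    "chi2",
    "n_eff",
    "maf",
]


class FormatError(ValueError):
    """A file violates one of the declared on-disk dialects."""


def chi2_from_p(p: np.ndarray) -> np.ndarray:
    """1-df chi-square quantile matching a two-sided p-value."""
    return sps.chi2.isf(np.asarray(p, dtype=float), df=1)


def p_from_chi2(chi2: np.ndarray) -> np.ndarray:
    """Two-sided p-value of a squared marginal Z statistic."""
    return sps.chi2.sf(np.asarray(chi2, dtype=float), df=1)


@dataclass
class SummaryStats:
    """Per-SNP marginal GWAS results.

    ``table`` holds one row per SNP with columns :data:`SUMSTATS_COLUMNS`.
    ``beta`` is the per-effect-allele effect on the trait scale, ``chi2``
    the squared marginal Z, ``n_eff`` the effective GWAS sample size per
    SNP, and ``maf`` the allele-agnostic minor allele frequency. Columns
    not supplied by a given dialect are NaN/None.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.table.columns]
        for col in missing:
            self.table[col] = np.nan
        self.table = self.table[SUMSTATS_COLUMNS].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        t = self.table
        dup = t["snp_id"][t["snp_id"].duplicated()]
        if len(dup):
            raise FormatError(f"duplicate snp_id: {dup.iloc[0]!r}")
        chi2 = t["chi2"].to_numpy(dtype=float)
        if np.any(chi2[np.isfinite(chi2)] < 0):
            raise ValueError("chi2 must be non-negative")
        p = t["p_value"].to_numpy(dtype=float)
        both = np.isfinite(chi2) & np.isfinite(p)
        if both.any():
            err = np.abs(p[both] - p_from_chi2(chi2[both]))
            if np.nanmax(err) >= 1e-8:
                raise ValueError("p_value inconsistent with 1-df chi-square of chi2")

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)

    def sorted_by_position(self) -> "SummaryStats":
        t = self.table.sort_values(["chrom", "pos", "snp_id"], kind="mergesort")
        return SummaryStats(t.reset_index(drop=True))

    def subset(self, snp_ids: Iterable[str]) -> "SummaryStats":
        keep = set(snp_ids)
        t = self.table[self.table["snp_id"].isin(keep)]
        return SummaryStats(t.reset_index(drop=True))

    def pvals(self) -> pd.Series:
        return self.table.set_index("snp_id")["p_value"]

    def betas(self) -> pd.Series:
        return self.table.set_index("snp_id")["beta"]


@dataclass
class GenotypeMatrix:
    """Dosage matrix (samples x SNPs) counting copies of the effect allele.

    ``variants`` carries per-SNP metadata (snp_id, chrom, pos,
    effect_allele, other_allele). Missing calls use :data:`MISSING`.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    population_label: str = ""

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} SNPs"
            )
        valid = ((self.dosages >= 0) & (self.dosages <= 2)) | (self.dosages == MISSING)
        if not valid.all():
            bad = self.dosages[~valid].ravel()[0]
            raise ValueError(f"invalid dosage value {bad}; must be 0/1/2 or missing")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.variants["snp_id"].to_numpy()

    def allele_freq(self) -> np.ndarray:
        """Effect-allele frequency per SNP, ignoring missing entries."""
        d = self.dosages.astype(float)
        d[self.dosages == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def dosage_float(self) -> np.ndarray:
        """Dosages as float with missing entries as NaN."""
        d = self.dosages.astype(float)
        d[self.dosages == MISSING] = np.nan
        return d

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = pd.Index(self.variants["snp_id"])
        pos = idx.get_indexer(list(snp_ids))
        if (pos < 0).any():
            missing = [s for s, q in zip(snp_ids, pos) if q < 0]
            raise KeyError(f"SNPs absent from genotypes: {missing[:5]}")
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=self.variants.iloc[pos].reset_index(drop=True),
            dosages=self.dosages[:, pos],
            population_label=self.population_label,
        )


@dataclass
class AnnotationTrack:
    """One tissue model's continuous per-SNP regulatory scores.

    ``raw_score`` is the regulatory probability in [0, 1]; ``norm_score``
    its quantile-normalized value and ``bin`` its percentile bin (1 = top
    of the distribution) once populated by the annotate module.
    """

    tissue_label: str
    snp_ids: np.ndarray
    raw_score: np.ndarray
    norm_score: np.ndarray | None = None
    bin: np.ndarray | None = None
    n_bins: int | None = None

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids)
        self.raw_score = np.asarray(self.raw_score, dtype=float)
        if self.snp_ids.shape != self.raw_score.shape:
            raise ValueError("snp_ids and raw_score must be aligned")

    def __len__(self) -> int:
        return len(self.snp_ids)


@dataclass
class CovariateTable:
    """Per-sample covariates: age, sex, pc1..pc10 and the coding PRS.

    The coding_prs column is zero until filled by the prs module.
    """

    frame: pd.DataFrame

    REQUIRED = ["age", "sex"]

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ValueError(f"covariate table missing column {col!r}")
        if "coding_prs" not in self.frame.columns:
            self.frame["coding_prs"] = 0.0
        if self.frame.isna().any().any():
            raise ValueError("covariate table contains missing values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index.astype(str))

    def design_columns(self, include_coding: bool = True) -> pd.DataFrame:
        cols = ["age", "sex"] + [c for c in self.frame.columns if c.startswith("pc")]
        if include_coding:
            cols.append("coding_prs")
        return self.frame[cols]

    def with_coding(self, scores: np.ndarray) -> "CovariateTable":
        frame = self.frame.copy()
        frame["coding_prs"] = np.asarray(scores, dtype=float)
        return CovariateTable(frame)

    def subset(self, idx: np.ndarray) -> "CovariateTable":
        return CovariateTable(self.frame.iloc[idx].copy())


@dataclass(frozen=True)
class Partition:
    """A selector-defined SNP subset of one tissue's annotation track.

    ``selector`` is either ``("top", f)`` for the top fraction f of the
    normalized score distribution, or ``("bin", b)`` for percentile bin b.
    """

    tissue_label: str
    selector: tuple[str, float]
    snp_ids: frozenset[str]

    def __len__(self) -> int:
        return len(self.snp_ids)


@dataclass
class TitrLogEntry:
    """One accepted iteration of the iterative tissue-refinement loop."""

    iteration: int
    tissue: str
    bin: int
    p_threshold: float
    n_added: int
    n_cumulative: int
    delta_r2_train: float
    selection_p: float
    delta_r2_valid: float = np.nan
    snps_added: tuple[str, ...] = ()


@dataclass
class TitrLog:
    """Ordered per-iteration records plus the cumulative model SNP set."""

    entries: list[TitrLogEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, e in enumerate(self.entries, start=1):
            if e.iteration != i:
                raise ValueError(
                    f"iteration numbers must be 1,2,...; got {e.iteration} at row {i}"
                )

    def append(self, entry: TitrLogEntry) -> None:
        expected = len(self.entries) + 1
        if entry.iteration != expected:
            raise ValueError(f"expected iteration {expected}, got {entry.iteration}")
        self.entries.append(entry)

    def model_snps(self, up_to: int | None = None) -> set[str]:
        out: set[str] = set()
        for e in self.entries:
            if up_to is not None and e.iteration > up_to:
                break
            out.update(e.snps_added)
        return out

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        cols = [f.name for f in dataclasses.fields(TitrLogEntry) if f.name != "snps_added"]
        return pd.DataFrame([{c: getattr(e, c) for c in cols} for e in self.entries],
                            columns=cols)
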