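"""Two-population synthetic study generator.

Emulates the study design the package targets: a large training
(European-like) population with long, strong LD and a genetically
distinct target (African-like) population with shorter, weaker LD; a set
of tissue-specific regulatory annotation tracks whose top percentiles
are enriched for causal SNPs in a small number of "true" tissues;
quantitative or 4:1-control:case binary phenotypes; and marginal GWAS
summary statistics computed in the training population.

Haplotypes come from a block-latent-Gaussian model: within an LD block
the latent variables follow an AR(1) process with population-specific
correlation, thresholded at each SNP's allele-frequency quantile. This
is an emulation giving exact control over the population LD contrast, not
a population-genetic simulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotate import assign_bins, quantile_normalize
from .datamodel import AnnotationTrack, CovariateTable, GenotypeMatrix, SummaryStats
from .prs import compute_pcs
from .ldsc import LdScoreTable

logger = logging.getLogger(__name__)

#: ENCODE-style organ/tissue labels for the 51 tissue models.
TISSUE_LABELS = [
    "adipose", "adrenal_gland", "blood", "blood_vessel", "bone", "bone_marrow",
    "brain", "breast", "bronchus", "colon", "connective_tissue", "ear",
    "embryo", "endocrine_gland", "epithelium", "esophagus", "extraembryonic",
    "eye", "gonad", "heart", "intestine", "kidney", "large_intestine",
    "limb", "liver", "lung", "lymph_node", "lymphoid_tissue", "mammary_gland",
    "mouth", "muscle", "musculature", "nerve", "nose", "ovary", "pancreas",
    "penis", "placenta", "prostate_gland", "skin", "small_intestine",
    "spinal_cord", "spleen", "stomach", "testis", "thymus", "thyroid_gland",
    "trachea", "urinary_bladder", "uterus", "vagina",
]

_POP_CODE = {"train": 11, "target": 22, "panel": 33}


@dataclass
class SimConfig:
    """Study conditions for the synthetic two-population design.

    Defaults are a desk-scale rendition of the real study: strong
    training-population LD (rho 0.95) against weaker target LD (rho 0.4),
    51 tissue tracks of which two are causal with 20-fold concentration
    of causal SNPs in their top 1% bins, a common-variant MAF floor of
    5%, and a 4:1 control:case ratio for binary traits.
    """

    seed: int = 0
    n_snps: int = 15000
    n_blocks: int = 1500
    block_rho_train: float = 0.95
    block_rho_target: float = 0.4
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_gwas: int = 8000
    n_train: int = 4000
    n_valid: int = 2000
    n_panel: int = 500
    h2: float = 0.7
    n_causal: int = 1500
    causal_tissues: tuple[str, ...] = ("adipose", "pancreas")
    enrichment: float = 20.0
    n_tissues: int = 51
    trait_type: str = "quantitative"
    prevalence: float = 0.1
    control_case_ratio: float = 4.0
    coding_fraction: float = 0.05
    snp_spacing_bp: int = 10000

    def __post_init__(self) -> None:
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal exceeds n_snps")
        if not set(self.causal_tissues) <= set(TISSUE_LABELS[:self.n_tissues]):
            raise ValueError("causal_tissues not among generated tissue labels")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")

    @property
    def tissue_labels(self) -> list[str]:
        return TISSUE_LABELS[:self.n_tissues]


def _rng(config: SimConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, *stream]))


def variant_metadata(config: SimConfig) -> pd.DataFrame:
    """Shared SNP metadata (positions, alleles, MAFs) for both populations."""
    rng = _rng(config, 1)
    m = config.n_snps
    maf = rng.uniform(*config.maf_range, size=m)
    alleles = np.array([("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")])
    pick = rng.integers(0, len(alleles), size=m)
    return pd.DataFrame({
        "snp_id": [f"rs{i + 1:06d}" for i in range(m)],
        "chrom": 1,
        "pos": (np.arange(m) + 1) * config.snp_spacing_bp,
        "effect_allele": alleles[pick, 0],
        "other_allele": alleles[pick, 1],
        "maf": maf,
        "block": np.minimum(np.arange(m) // max(1, m // config.n_blocks),
                            config.n_blocks - 1),
    })


def _latent_haplotypes(rng: np.random.Generator, n: int, block_sizes: np.ndarray,
                       rho: float) -> np.ndarray:
    """AR(1) latent Gaussians per block: corr(i, j) = rho^|i-j| within a block."""
    from scipy.signal import lfilter

    total = int(block_sizes.sum())
    # float32 halves memory and time; thresholded to 0/1 immediately after
    z = rng.standard_normal((n, total), dtype=np.float32)
    if rho == 0.0:
        return z
    scale = np.float32(np.sqrt(1.0 - rho ** 2))
    starts = np.concatenate([[0], np.cumsum(block_sizes)[:-1]])
    z *= scale
    z[:, starts] /= scale  # block-leading SNPs are unit-variance seeds
    b = np.array([1.0], dtype=z.dtype)  # float32 coefficients keep lfilter in float32
    a_coef = np.array([1.0, -rho], dtype=z.dtype)
    if len(set(block_sizes)) == 1:
        bs = int(block_sizes[0])
        shaped = z.reshape(n, -1, bs)
        return lfilter(b, a_coef, shaped, axis=2).reshape(n, total)
    out = np.empty_like(z)
    for start, size in zip(starts, block_sizes):
        sl = slice(start, start + size)
        out[:, sl] = lfilter(b, a_coef, z[:, sl], axis=1)
    return out


def simulate_genotypes(config: SimConfig, population: str,
                       n: int | None = None) -> GenotypeMatrix:
    """Dosages for one population: sum of two thresholded latent haplotypes.

    ``population`` is ``train``, ``target`` (each with its configured
    within-block correlation) or ``panel`` (an independent draw from the
    training-population LD structure, for use as an LD reference).
    """
    if population not in _POP_CODE:
        raise ValueError(f"unknown population {population!r}")
    rho = (config.block_rho_target if population == "target"
           else config.block_rho_train)
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"block rho must be in [0, 1), got {rho}")
    if n is None:
        n = {"train": config.n_train, "target": config.n_valid,
             "panel": config.n_panel}[population]
    if n < 2:
        raise ValueError("need at least 2 samples")
    meta = variant_metadata(config)
    block_sizes = meta["block"].value_counts().sort_index().to_numpy()
    thresh = sps.norm.ppf(meta["maf"].to_numpy()).astype(np.float32)
    rng = _rng(config, _POP_CODE[population], n)
    dosages = (_latent_haplotypes(rng, n, block_sizes, rho) < thresh).astype(np.int8)
    dosages += _latent_haplotypes(rng, n, block_sizes, rho) < thresh
    sample_ids = [f"{population}_{i:06d}" for i in range(n)]
    variants = meta[["snp_id", "chrom", "pos", "effect_allele", "other_allele"]]
    return GenotypeMatrix(sample_ids, variants, dosages, population_label=population)


def choose_causal(config: SimConfig) -> tuple[list[str], np.ndarray]:
    """Causal SNP ids and their standardized effect sizes.

    Effects have fixed magnitude sqrt(h2 / n_causal) with random sign, so
    every causal SNP carries an equal share h2 / n_causal of heritability
    — the per-SNP heritability model the annotation enrichment is defined
    against.
    """
    meta = variant_metadata(config)
    rng = _rng(config, 2)
    idx = rng.choice(config.n_snps, size=config.n_causal, replace=False)
    idx.sort()
    signs = rng.choice([-1.0, 1.0], size=config.n_causal)
    betas = signs * np.sqrt(config.h2 / config.n_causal)
    return list(meta["snp_id"].iloc[idx]), betas


def choose_coding(config: SimConfig) -> set[str]:
    """A random "coding-region" SNP mask (a stand-in for a real gene map)."""
    meta = variant_metadata(config)
    rng = _rng(config, 3)
    k = int(round(config.coding_fraction * config.n_snps))
    idx = rng.choice(config.n_snps, size=k, replace=False)
    return set(meta["snp_id"].iloc[idx])


def simulate_annotations(config: SimConfig,
                         causal_snps: set[str]) -> list[AnnotationTrack]:
    """Tissue annotation tracks with causal enrichment in the true tissues.

    For each causal tissue, causal SNPs draw their score *quantile* from
    the skewed law q = 1 - u^a with a = ln(0.01) / ln(min(1, enrichment *
    0.01)), so the probability of landing in the top 1% of the
    distribution equals enrichment * 0.01 exactly while every higher
    percentile band is enriched in a graded fashion — emulating tissue
    annotations whose top percentiles concentrate progressively more
    heritability. enrichment = 1 gives a = 1, i.e. no enrichment.
    Non-causal tissues score independently of causal status. Raw
    marginals are Beta(1, 4); all tracks are then quantile normalized
    and binned at 0.1% resolution.
    """
    if config.enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    meta = variant_metadata(config)
    snp_ids = meta["snp_id"].to_numpy()
    if not causal_snps <= set(snp_ids):
        raise ValueError("causal_snps not a subset of simulated SNPs")
    causal_mask = np.isin(snp_ids, list(causal_snps))
    causal_idx = np.flatnonzero(causal_mask)
    rng = _rng(config, 4)
    q_top = min(1.0, config.enrichment * 0.01)
    a = np.inf if q_top >= 1.0 else np.log(0.01) / np.log(q_top)
    m = config.n_snps
    tracks = []
    for tissue in config.tissue_labels:
        quantile = rng.uniform(size=m)
        if tissue in config.causal_tissues and config.enrichment > 1:
            # stratified draw: one quantile per equal-mass stratum of the
            # skewed law, randomly assigned, so every realization carries
            # the nominal enrichment profile exactly
            nc = len(causal_idx)
            u = (np.arange(nc) + rng.uniform(size=nc)) / nc
            if np.isinf(a):  # every causal SNP sits in the top 1%
                qc = 0.99 + 0.01 * u
            else:
                qc = 1.0 - u ** a
            quantile[causal_idx] = rng.permutation(qc)
        # Beta(1, 4) quantile function in closed form: F(x) = 1 - (1-x)^4
        raw = 1.0 - (1.0 - quantile) ** 0.25
        tracks.append(AnnotationTrack(tissue, snp_ids, raw))
    tracks = quantile_normalize(tracks)
    return [assign_bins(t) for t in tracks]


def simulate_phenotype(genotypes: GenotypeMatrix, config: SimConfig,
                       effects: dict[str, float], with_covariates: bool = True
                       ) -> tuple[np.ndarray, CovariateTable | None, np.ndarray]:
    """Phenotype and covariates for one cohort.

    y = standardized-dosage genetic value (scaled to variance h2) + small
    fixed age/sex effects + N(0, 1 - h2) noise. Binary traits threshold
    the liability at the (1 - prevalence) empirical quantile and subsample
    controls to the configured control:case ratio. Returns (phenotype,
    covariates, kept sample indices); for quantitative traits all samples
    are kept.
    """
    n = genotypes.n_samples
    rng = _rng(config, 5, _POP_CODE.get(genotypes.population_label, 0), n)
    g = np.zeros(n)
    if effects and config.h2 > 0:
        snps = [s for s in effects if s in set(genotypes.snp_ids)]
        sub = genotypes.subset_snps(snps)
        d = sub.dosage_float()
        mean = np.nanmean(d, axis=0)
        sd = np.nanstd(d, axis=0)
        ok = sd > 0
        ds = np.nan_to_num((d[:, ok] - mean[ok]) / sd[ok])
        g = ds @ np.array([effects[s] for s in np.array(snps)[ok]])
        if g.std() > 0:
            g = g / g.std() * np.sqrt(config.h2)
    age = rng.normal(50.0, 10.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    noise = rng.normal(0.0, np.sqrt(max(1.0 - config.h2, 1e-12)), size=n)
    liability = g + 0.05 * (age - 50.0) / 10.0 + 0.05 * (sex - 0.5) + noise

    pcs_cov = _covariates(genotypes, age, sex) if with_covariates else None
    if config.trait_type == "quantitative":
        return liability, pcs_cov, np.arange(n)

    cut = np.quantile(liability, 1.0 - config.prevalence)
    case = liability > cut
    n_cases = int(case.sum())
    n_controls = int(np.floor(config.control_case_ratio) * n_cases)
    controls = np.flatnonzero(~case)
    if len(controls) < n_controls:
        raise ValueError(
            f"only {len(controls)} controls available; ratio requires {n_controls}")
    kept_controls = rng.choice(controls, size=n_controls, replace=False)
    kept = np.sort(np.concatenate([np.flatnonzero(case), kept_controls]))
    y = case[kept].astype(float)
    return y, pcs_cov.subset(kept) if pcs_cov is not None else None, kept


def _covariates(genotypes: GenotypeMatrix, age: np.ndarray,
                sex: np.ndarray) -> CovariateTable:
    pcs = compute_pcs(genotypes, k=10)
    frame = pd.DataFrame({"age": age, "sex": sex},
                         index=pd.Index(genotypes.sample_ids, name="sample_id"))
    for i in range(10):
        frame[f"pc{i + 1}"] = pcs[:, i]
    return CovariateTable(frame)


def simulate_gwas(genotypes: GenotypeMatrix, phenotype: np.ndarray) -> SummaryStats:
    """Marginal per-SNP least-squares association scan.

    Returns both summary-statistic views (beta/p and chi2/N). Monomorphic
    SNPs are dropped with a logged count.
    """
    n = genotypes.n_samples
    if n < 50:
        raise ValueError("GWAS cohort must have at least 50 samples")
    y = np.asarray(phenotype, dtype=float)
    if len(y) != n:
        raise ValueError("phenotype length does not match cohort")
    m = genotypes.n_snps
    n_obs = np.empty(m)
    sx = np.empty(m)
    sy = np.empty(m)
    sxx = np.empty(m)
    sxy = np.empty(m)
    syy = np.empty(m)
    from .datamodel import MISSING

    any_missing = bool((genotypes.dosages == MISSING).any())
    for lo in range(0, m, 4096):  # chunked to bound peak memory on large cohorts
        sl = slice(lo, min(lo + 4096, m))
        d = genotypes.dosages[:, sl]
        if not any_missing:
            xz = d.astype(float)
            n_obs[sl] = n
            sy[sl] = y.sum()
            syy[sl] = y @ y
        else:
            x = d.astype(float)
            x[d == MISSING] = np.nan
            obs = np.isfinite(x)
            n_obs[sl] = obs.sum(axis=0)
            xz = np.nan_to_num(x)
            sy[sl] = y @ obs
            syy[sl] = (y ** 2) @ obs
        sx[sl] = xz.sum(axis=0)
        sxx[sl] = np.einsum("ij,ij->j", xz, xz)
        sxy[sl] = y.astype(xz.dtype) @ xz
    with np.errstate(divide="ignore", invalid="ignore"):
        sxx_c = sxx - sx ** 2 / n_obs
        sxy_c = sxy - sx * sy / n_obs
        syy_c = syy - sy ** 2 / n_obs
        beta = sxy_c / sxx_c
        df = n_obs - 2
        sigma2 = np.maximum(syy_c - beta * sxy_c, 0.0) / df
        se = np.sqrt(sigma2 / sxx_c)
        tstat = beta / se
    mono = ~np.isfinite(beta) | (sxx_c <= 0)
    if mono.any():
        logger.info("simulate_gwas: dropped %d monomorphic SNPs", int(mono.sum()))
    p = 2 * sps.t.sf(np.abs(tstat), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    freq = genotypes.allele_freq()
    table = pd.DataFrame({
        "snp_id": genotypes.snp_ids,
        "chrom": genotypes.variants["chrom"],
        "pos": genotypes.variants["pos"],
        "effect_allele": genotypes.variants["effect_allele"],
        "other_allele": genotypes.variants["other_allele"],
        "beta": beta,
        "p_value": p,
        "chi2": np.asarray(tstat) ** 2,
        "n_eff": n_obs.astype(float),
        "maf": np.minimum(freq, 1 - freq),
    })[~mono]
    # keep p exactly consistent with the 1-df chi-square of t^2 so both
    # summary-statistic dialects agree on every record
    table["p_value"] = sps.chi2.sf(table["chi2"], df=1)
    return SummaryStats(table.reset_index(drop=True))


def simulate_chi2_from_ld_scores(lds: LdScoreTable, tau: np.ndarray,
                                 n_eff: float, seed: int,
                                 intercept: float = 1.0) -> SummaryStats:
    """Model-consistent summary statistics drawn from LD scores.

    Each Z is N(0, intercept + N * sum_C tau_C ell_jC); chi2 = Z^2. Used
    for calibration studies of the stratified regression itself.
    """
    rng = np.random.default_rng(seed)
    var = intercept + n_eff * lds.ell @ np.asarray(tau, dtype=float)
    if (var <= 0).any():
        raise ValueError("negative chi2 variance implied by tau")
    z = rng.standard_normal(len(var)) * np.sqrt(var)
    chi2 = z ** 2
    m = len(chi2)
    table = pd.DataFrame({
        "snp_id": lds.snp_ids,
        "chrom": lds.chrom if lds.chrom is not None else np.ones(m, dtype=int),
        "pos": lds.pos if lds.pos is not None else np.arange(1, m + 1),
        "effect_allele": "A", "other_allele": "G",
        "beta": np.nan,
        "p_value": sps.chi2.sf(chi2, df=1),
        "chi2": chi2,
        "n_eff": float(n_eff),
        "maf": np.nan,
    })
    return SummaryStats(table)


@dataclass
class SimStudy:
    """Everything one end-to-end study needs, plus the generating truth."""

    config: SimConfig
    panel: GenotypeMatrix
    gwas_stats: SummaryStats
    train: GenotypeMatrix
    train_phenotype: np.ndarray
    train_covariates: CovariateTable
    target: GenotypeMatrix
    target_phenotype: np.ndarray
    target_covariates: CovariateTable
    tracks: list[AnnotationTrack]
    causal_snps: list[str]
    causal_betas: np.ndarray
    coding_snps: set[str] = field(default_factory=set)


def simulate_study(config: SimConfig) -> SimStudy:
    """Generate the full two-population study bundle under one seed."""
    causal, betas = choose_causal(config)
    effects = dict(zip(causal, betas))

    gwas_geno = simulate_genotypes(config, "train", n=config.n_gwas)
    gwas_pheno, _, kept = simulate_phenotype(gwas_geno, config, effects,
                                             with_covariates=False)
    if config.trait_type == "binary":
        gwas_geno = GenotypeMatrix(
            [gwas_geno.sample_ids[i] for i in kept], gwas_geno.variants,
            gwas_geno.dosages[kept], gwas_geno.population_label)
    stats = simulate_gwas(gwas_geno, gwas_pheno)

    panel = simulate_genotypes(config, "panel")

    train = simulate_genotypes(config, "train", n=config.n_train)
    train_pheno, train_cov, kept_tr = simulate_phenotype(train, config, effects)
    if config.trait_type == "binary":
        train = GenotypeMatrix([train.sample_ids[i] for i in kept_tr],
                               train.variants, train.dosages[kept_tr],
                               train.population_label)

    target = simulate_genotypes(config, "target", n=config.n_valid)
    target_pheno, target_cov, kept_tg = simulate_phenotype(target, config, effects)
    if config.trait_type == "binary":
        target = GenotypeMatrix([target.sample_ids[i] for i in kept_tg],
                                target.variants, target.dosages[kept_tg],
                                target.population_label)

    tracks = simulate_annotations(config, set(causal))
    return SimStudy(
        config=config, panel=panel, gwas_stats=stats,
        train=train, train_phenotype=train_pheno, train_covariates=train_cov,
        target=target, target_phenotype=target_pheno, target_covariates=target_cov,
        tracks=tracks, causal_snps=causal, causal_betas=betas,
        coding_snps=choose_coding(config),
    )
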