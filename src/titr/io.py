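"""Readers and writers for the package's on-disk formats.

Two whitespace-delimited summary-statistics dialects are supported:

* ``heritability`` — columns ``SNP A1 A2 N CHISQ`` (rsID, reference allele,
  alternative allele, effective per-SNP GWAS sample size, chi-square
  statistic derived from the GWAS betas), used for heritability
  partitioning;
* ``scoring`` — columns ``SNP A1 BETA P`` (rsID, effect allele, effect
  size estimate, association p-value), used for allelic scoring.

Optional columns ``CHR``, ``BP``, ``MAF`` are honoured in both dialects.

Genotypes travel either as PLINK bed/bim/fam triplets or as the package's
plain-text dosage dialect: ``<prefix>.dosage.tsv`` is a samples-by-SNPs
table (first column ``sample_id``, one column per SNP, values 0/1/2 or
``NA``) and ``<prefix>.vars.tsv`` is the companion variant-metadata table
(snp_id, chrom, pos, effect_allele, other_allele). All text files are
UTF-8 with a mandatory header row.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    AMBIGUOUS_PAIRS,
    MISSING,
    VALID_ALLELES,
    AnnotationTrack,
    CovariateTable,
    FormatError,
    GenotypeMatrix,
    SummaryStats,
    TitrLog,
    TitrLogEntry,
    chi2_from_p,
    p_from_chi2,
)

logger = logging.getLogger(__name__)

_DIALECTS = {
    "heritability": {"SNP": "snp_id", "A1": "effect_allele", "A2": "other_allele",
                     "N": "n_eff", "CHISQ": "chi2"},
    "scoring": {"SNP": "snp_id", "A1": "effect_allele", "BETA": "beta", "P": "p_value"},
}
_OPTIONAL = {"CHR": "chrom", "BP": "pos", "MAF": "maf"}


def read_sumstats(path: str | Path, dialect: str) -> SummaryStats:
    """Read a summary-statistics file in one of the two Methods dialects.

    Derived fields are back-filled: ``chi2`` from ``p_value`` (and vice
    versa) via the 1-df chi-square. Rows with unparseable alleles or
    p outside (0, 1] are dropped with a logged count.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    mapping = _DIALECTS[dialect]
    df = pd.read_csv(path, sep=r"\s+", dtype={"SNP": str},
                     float_precision="round_trip")
    for col in mapping:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} for dialect {dialect!r}")
    rename = {**mapping, **{c: t for c, t in _OPTIONAL.items() if c in df.columns}}
    df = df[list(rename)].rename(columns=rename)

    n0 = len(df)
    allele_cols = [c for c in ("effect_allele", "other_allele") if c in df.columns]
    keep = np.ones(n0, dtype=bool)
    for c in allele_cols:
        df[c] = df[c].astype(str).str.upper()
        keep &= df[c].isin(list(VALID_ALLELES)).to_numpy()
    if "p_value" in df.columns:
        p = pd.to_numeric(df["p_value"], errors="coerce").to_numpy(dtype=float)
        keep &= np.isfinite(p) & (p > 0) & (p <= 1)
    dropped = int(n0 - keep.sum())
    if dropped:
        logger.info("read_sumstats: dropped %d rows with invalid alleles or p-values", dropped)
    df = df[keep].reset_index(drop=True)

    if "p_value" in df.columns and "chi2" not in df.columns:
        df["chi2"] = chi2_from_p(df["p_value"].to_numpy(dtype=float))
    if "chi2" in df.columns and "p_value" not in df.columns:
        df["p_value"] = p_from_chi2(df["chi2"].to_numpy(dtype=float))
    return SummaryStats(df)


def write_sumstats(stats: SummaryStats, path: str | Path, dialect: str) -> None:
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    mapping = _DIALECTS[dialect]
    t = stats.table
    out = pd.DataFrame({src: t[dst] for src, dst in mapping.items()})
    for src, dst in _OPTIONAL.items():
        if t[dst].notna().any():
            out[src] = t[dst]
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path: str | Path, format: str = "dosage_text",
                   population_label: str = "") -> GenotypeMatrix:
    """Read genotypes from a file prefix in the given format."""
    if format == "dosage_text":
        return _read_dosage_text(Path(path), population_label)
    if format == "plink_bed":
        return _read_plink_bed(Path(path), population_label)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(geno: GenotypeMatrix, path: str | Path,
                    format: str = "dosage_text") -> None:
    if format == "dosage_text":
        _write_dosage_text(geno, Path(path))
    elif format == "plink_bed":
        _write_plink_bed(geno, Path(path))
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _read_dosage_text(prefix: Path, population_label: str) -> GenotypeMatrix:
    variants = pd.read_csv(f"{prefix}.vars.tsv", sep="\t", dtype={"snp_id": str})
    for col in ("snp_id", "chrom", "pos", "effect_allele", "other_allele"):
        if col not in variants.columns:
            raise FormatError(f"variant file missing mandatory column {col!r}")
    bad = ~variants["effect_allele"].isin(list(VALID_ALLELES)) | ~variants[
        "other_allele"].isin(list(VALID_ALLELES))
    if bad.any():
        raise FormatError(
            f"unknown allele code for SNP {variants.loc[bad, 'snp_id'].iloc[0]!r}")
    dos = pd.read_csv(f"{prefix}.dosage.tsv", sep="\t", dtype={"sample_id": str})
    if "sample_id" not in dos.columns:
        raise FormatError("dosage file missing mandatory column 'sample_id'")
    sample_ids = dos["sample_id"].tolist()
    snp_cols = [c for c in dos.columns if c != "sample_id"]
    if snp_cols != variants["snp_id"].tolist():
        raise FormatError("dosage columns do not match variant file SNP ids")
    mat = dos[snp_cols].to_numpy(dtype=float)
    out = np.full(mat.shape, MISSING, dtype=np.int8)
    ok = np.isfinite(mat)
    out[ok] = mat[ok].astype(np.int8)
    return GenotypeMatrix(sample_ids, variants, out, population_label)


def _write_dosage_text(geno: GenotypeMatrix, prefix: Path) -> None:
    geno.variants.to_csv(f"{prefix}.vars.tsv", sep="\t", index=False)
    d = geno.dosages.astype(object)
    d[geno.dosages == MISSING] = "NA"
    frame = pd.DataFrame(d, columns=geno.snp_ids)
    frame.insert(0, "sample_id", geno.sample_ids)
    frame.to_csv(f"{prefix}.dosage.tsv", sep="\t", index=False)


# PLINK .bed codec (SNP-major): 2 bits per call, 00=2 copies of bim allele
# 1, 10=1 copy, 11=0 copies, 01=missing. The counted (effect) allele is
# bim column 5, matching PLINK's A1 convention.
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
_BED_DECODE = {0b00: 2, 0b01: MISSING, 0b10: 1, 0b11: 0}
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def _read_plink_bed(prefix: Path, population_label: str) -> GenotypeMatrix:
    bim = pd.read_csv(f"{prefix}.bim", sep=r"\s+", header=None,
                      names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
                      dtype={"snp_id": str, "a1": str, "a2": str})
    fam = pd.read_csv(f"{prefix}.fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"],
                      dtype={"iid": str})
    bad = ~bim["a1"].str.upper().isin(list(VALID_ALLELES)) | ~bim["a2"].str.upper().isin(
        list(VALID_ALLELES))
    if bad.any():
        raise FormatError(f"unknown allele code for SNP {bim.loc[bad, 'snp_id'].iloc[0]!r}")
    n, m = len(fam), len(bim)
    raw = Path(f"{prefix}.bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError("not a SNP-major PLINK .bed file")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if len(body) != bytes_per_snp * m:
        raise FormatError(
            f".bed payload of {len(body)} bytes does not match {n} samples x {m} SNPs")
    codes = body.reshape(m, bytes_per_snp)
    # unpack 2-bit fields, low bits first within each byte
    shifts = np.arange(4) * 2
    two_bit = (codes[:, :, None] >> shifts[None, None, :]) & 0b11
    two_bit = two_bit.reshape(m, -1)[:, :n]
    lut = np.empty(4, dtype=np.int8)
    for code, dosage in _BED_DECODE.items():
        lut[code] = dosage
    dosages = lut[two_bit].T  # samples x SNPs
    variants = pd.DataFrame({
        "snp_id": bim["snp_id"],
        "chrom": bim["chrom"].astype(int),
        "pos": bim["pos"].astype(int),
        "effect_allele": bim["a1"].str.upper(),
        "other_allele": bim["a2"].str.upper(),
    })
    return GenotypeMatrix(fam["iid"].tolist(), variants, dosages, population_label)


def _write_plink_bed(geno: GenotypeMatrix, prefix: Path) -> None:
    v = geno.variants
    bim = pd.DataFrame({
        "chrom": v["chrom"], "snp_id": v["snp_id"], "cm": 0, "pos": v["pos"],
        "a1": v["effect_allele"], "a2": v["other_allele"],
    })
    bim.to_csv(f"{prefix}.bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame({
        "fid": geno.sample_ids, "iid": geno.sample_ids, "pat": 0, "mat": 0,
        "sex": 0, "pheno": -9,
    })
    fam.to_csv(f"{prefix}.fam", sep="\t", header=False, index=False)
    n, m = geno.n_samples, geno.n_snps
    lut = np.empty(256, dtype=np.uint8)  # dosage int8 -> 2-bit code
    for dosage, code in _BED_ENCODE.items():
        lut[np.int8(dosage).view(np.uint8)] = code
    codes = lut[geno.dosages.T.view(np.uint8)]  # m x n
    pad = (-n) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.full((m, pad), _BED_ENCODE[0], dtype=np.uint8)], axis=1)
    shifts = np.arange(4) * 2
    packed = (codes.reshape(m, -1, 4) << shifts[None, None, :]).sum(axis=2).astype(np.uint8)
    Path(f"{prefix}.bed").write_bytes(_BED_MAGIC + packed.tobytes())


# ---------------------------------------------------------------------------
# annotations, covariates


def read_annotations(path: str | Path) -> list[AnnotationTrack]:
    """Read a tab-delimited annotation table: snp_id + one column per tissue.

    Binned tables written by :func:`write_annotations` carry companion
    ``<tissue>__bin`` and ``<tissue>__norm`` columns, which are restored.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str},
                     float_precision="round_trip")
    if "snp_id" not in df.columns:
        raise FormatError("annotation table missing mandatory column 'snp_id'")
    snp_ids = df["snp_id"].to_numpy()
    tissues = [c for c in df.columns if c != "snp_id" and "__" not in c]
    tracks = []
    for t in tissues:
        track = AnnotationTrack(t, snp_ids, df[t].to_numpy(dtype=float))
        if f"{t}__norm" in df.columns:
            track.norm_score = df[f"{t}__norm"].to_numpy(dtype=float)
        if f"{t}__bin" in df.columns:
            track.bin = df[f"{t}__bin"].to_numpy(dtype=int)
            track.n_bins = int(track.bin.max())
        tracks.append(track)
    return tracks


def write_annotations(tracks: list[AnnotationTrack], path: str | Path) -> None:
    if not tracks:
        raise ValueError("no tracks to write")
    data = {"snp_id": tracks[0].snp_ids}
    for t in tracks:
        if not np.array_equal(t.snp_ids, tracks[0].snp_ids):
            raise ValueError("tracks have mismatched SNP sets")
        data[t.tissue_label] = t.raw_score
        if t.norm_score is not None:
            data[f"{t.tissue_label}__norm"] = t.norm_score
        if t.bin is not None:
            data[f"{t.tissue_label}__bin"] = t.bin
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_covariates(path: str | Path) -> CovariateTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str},
                     float_precision="round_trip")
    if "sample_id" not in df.columns:
        raise FormatError("covariate table missing mandatory column 'sample_id'")
    return CovariateTable(df.set_index("sample_id"))


def write_covariates(cov: CovariateTable, path: str | Path) -> None:
    cov.frame.rename_axis("sample_id").to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# iteration log

_LOG_COLUMNS = ["iteration", "tissue", "bin", "p_threshold", "n_added",
                "n_cumulative", "delta_r2_train", "selection_p", "delta_r2_valid"]


def write_titr_log(log: TitrLog, path: str | Path) -> None:
    """Write the master model log plus a companion SNP-list file.

    ``<path>`` is the tab-delimited per-iteration table; ``<path>.snps``
    maps each iteration to the SNPs merged on that iteration.
    """
    path = Path(path)
    frame = log.to_frame()
    if frame.empty:
        frame = pd.DataFrame(columns=_LOG_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    with open(f"{path}.snps", "w") as fh:
        fh.write("iteration\tsnp_id\n")
        for e in log.entries:
            for s in e.snps_added:
                fh.write(f"{e.iteration}\t{s}\n")


def read_titr_log(path: str | Path) -> TitrLog:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in _LOG_COLUMNS:
        if col not in frame.columns:
            raise FormatError(f"model log missing mandatory column {col!r}")
    snps = pd.read_csv(f"{path}.snps", sep="\t", dtype={"snp_id": str})
    by_iter = snps.groupby("iteration")["snp_id"].apply(tuple).to_dict()
    entries = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        if row.iteration != i:
            raise FormatError(f"iteration gap in log: expected {i}, found {row.iteration}")
        entries.append(TitrLogEntry(
            iteration=int(row.iteration), tissue=str(row.tissue), bin=int(row.bin),
            p_threshold=float(row.p_threshold), n_added=int(row.n_added),
            n_cumulative=int(row.n_cumulative),
            delta_r2_train=float(row.delta_r2_train),
            selection_p=float(row.selection_p),
            delta_r2_valid=float(row.delta_r2_valid),
            snps_added=by_iter.get(i, ()),
        ))
    return TitrLog(entries)


# ---------------------------------------------------------------------------
# allele harmonization


def harmonize_stats_to_panel(stats: SummaryStats, geno: GenotypeMatrix) -> SummaryStats:
    """Align summary statistics to a genotype panel's counted alleles.

    When the stats effect allele is the panel's other allele, beta's sign
    is flipped and the alleles swapped. Strand-ambiguous SNPs (A/T, C/G)
    and allele mismatches are dropped with a logged count. The result is
    restricted to the intersection of SNP sets.
    """
    v = geno.variants.set_index("snp_id")
    t = stats.table.set_index("snp_id")
    shared = t.index.intersection(v.index)
    dropped_absent = len(t) - len(shared)
    t = t.loc[shared]
    v = v.loc[shared]

    ea, oa = t["effect_allele"].to_numpy(), t["other_allele"].to_numpy()
    pea, poa = v["effect_allele"].to_numpy(), v["other_allele"].to_numpy()
    ambiguous = np.array([(a, b) in AMBIGUOUS_PAIRS for a, b in zip(ea, oa)])
    # scoring dialect may omit the other allele: treat as matching on A1
    oa_known = pd.notna(oa)
    same = (ea == pea) & (~oa_known | (oa == poa))
    flipped = (ea == poa) & (~oa_known | (oa == pea))
    keep = ~ambiguous & (same | flipped)
    n_amb = int((ambiguous & (same | flipped)).sum())
    n_mismatch = int((~same & ~flipped).sum())
    if dropped_absent or n_amb or n_mismatch:
        logger.info(
            "harmonize: dropped %d absent, %d strand-ambiguous, %d mismatched SNPs",
            dropped_absent, n_amb, n_mismatch)

    t = t[keep].copy()
    flip = flipped[keep]
    t.loc[flip, "beta"] = -t.loc[flip, "beta"]
    t.loc[flip, ["effect_allele", "other_allele"]] = np.column_stack(
        [pea[keep][flip], poa[keep][flip]])
    return SummaryStats(t.reset_index())
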