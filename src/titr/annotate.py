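"""Quantile normalization, percentile binning and partition extraction.

Tissue-specific regulatory score distributions differ in shape, so SNP
partitions drawn at a fixed percentile would differ in size across
tissues. Quantile normalization maps every track onto the common grid
(rank - 0.5) / M, making percentile partitions equivalently sized, after
which each track is cut into B bins (default B = 1000, i.e. 0.1%
resolution) with bin 1 at the top of the distribution.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import rankdata

from .datamodel import AnnotationTrack, Partition

TOP_FRACTIONS = (0.01, 0.05, 0.10, 0.20, 0.50)


def quantile_normalize(tracks: list[AnnotationTrack]) -> list[AnnotationTrack]:
    """Map each track's raw scores to (rank - 0.5) / M; ties get average rank.

    All tracks must score the same SNP set. The multiset of normalized
    values is then identical across tracks and the transform is idempotent.
    """
    if not tracks:
        return []
    ref = tracks[0].snp_ids
    for t in tracks[1:]:
        if not np.array_equal(t.snp_ids, ref):
            raise ValueError(
                f"track {t.tissue_label!r} scores a different SNP set than "
                f"{tracks[0].tissue_label!r}")
    m = len(ref)
    out = []
    for t in tracks:
        norm = (rankdata(t.raw_score, method="average") - 0.5) / m
        out.append(AnnotationTrack(t.tissue_label, t.snp_ids, t.raw_score,
                                   norm_score=norm, bin=t.bin, n_bins=t.n_bins))
    return out


def _descending_order(track: AnnotationTrack) -> np.ndarray:
    """Indices sorting norm_score descending, ties broken by snp_id ascending.

    The deterministic tie-break makes bin boundaries independent of input
    order and of any simulation seed.
    """
    if track.norm_score is None:
        raise ValueError("norm_score not populated; run quantile_normalize first")
    return np.lexsort((track.snp_ids, -track.norm_score))


def assign_bins(track: AnnotationTrack, resolution: float = 0.001) -> AnnotationTrack:
    """Cut a normalized track into 1/resolution equally-sized percentile bins.

    Bin b holds the SNPs in the ((B-b)/B, (B-b+1)/B] quantile band of the
    normalized score, so bin 1 contains the highest scores. Bin sizes
    differ by at most one SNP.
    """
    n_bins = round(1.0 / resolution)
    if not math.isclose(n_bins * resolution, 1.0, rel_tol=1e-9):
        raise ValueError(f"resolution {resolution} does not divide 1 into integer bins")
    order = _descending_order(track)
    m = len(track)
    bins = np.empty(m, dtype=int)
    bins[order] = np.floor(np.arange(m) * n_bins / m).astype(int) + 1
    return AnnotationTrack(track.tissue_label, track.snp_ids, track.raw_score,
                           norm_score=track.norm_score, bin=bins, n_bins=n_bins)


def top_fraction_partition(track: AnnotationTrack, f: float) -> Partition:
    """The ceil(f * M) highest-scoring SNPs of a normalized track.

    Partitions are nested over f: partition(f1) is a subset of
    partition(f2) whenever f1 <= f2.
    """
    if not 0 < f <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {f}")
    order = _descending_order(track)
    k = math.ceil(f * len(track))
    return Partition(track.tissue_label, ("top", float(f)),
                     frozenset(track.snp_ids[order[:k]]))


def bin_partition(track: AnnotationTrack, b: int) -> Partition:
    """The SNPs of percentile bin b (1 = top of the distribution)."""
    if track.bin is None:
        raise ValueError("bins not populated; run assign_bins first")
    if not 1 <= b <= track.n_bins:
        raise ValueError(f"bin {b} outside 1..{track.n_bins}")
    return Partition(track.tissue_label, ("bin", float(b)),
                     frozenset(track.snp_ids[track.bin == b]))
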