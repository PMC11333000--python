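"""Greedy p-value clumping and one-SNP-per-LD-block sampling.

Clumping reproduces the PLINK algorithm: SNPs are ranked by ascending
GWAS p-value; the best unassigned SNP becomes an index variant and
absorbs every unassigned SNP within the physical window whose r2 with it
meets the threshold. Block sampling then draws at most one SNP per LD
block for a functional partition, preferring the index variant and
otherwise the partition member with the strongest association — the rule
that protects the cumulative model from over-sampling a single block
across iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import GenotypeMatrix, Partition, SummaryStats

logger = logging.getLogger(__name__)


@dataclass
class ClumpBlock:
    index_snp: str
    members: list[str]


@dataclass
class ClumpResult:
    """LD-block structure: index variants with their clumped members.

    ``unassigned`` holds SNPs excluded from clumping (p above the
    ceiling, or monomorphic in the panel); they are treated downstream
    as one-SNP blocks. ``pvals`` retains each SNP's GWAS p-value so
    block sampling can rank members without re-reading the GWAS.
    """

    blocks: list[ClumpBlock]
    r2_threshold: float
    window_kb: float
    unassigned: list[str] = field(default_factory=list)
    pvals: dict[str, float] = field(default_factory=dict)

    def block_of(self) -> dict[str, int]:
        """Map snp_id -> block ordinal (unassigned singletons included)."""
        out: dict[str, int] = {}
        for i, b in enumerate(self.blocks):
            out[b.index_snp] = i
            for s in b.members:
                out[s] = i
        n = len(self.blocks)
        for j, s in enumerate(self.unassigned):
            out[s] = n + j
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [{"index_snp": b.index_snp, "p": self.pvals.get(b.index_snp, np.nan),
                 "n_members": len(b.members), "members": ",".join(b.members) or "NONE"}
                for b in self.blocks]
        return pd.DataFrame(rows, columns=["index_snp", "p", "n_members", "members"])


def clump(stats: SummaryStats, panel: GenotypeMatrix, r2_threshold: float = 0.2,
          window_kb: float = 250.0, p_ceiling: float = 1.0) -> ClumpResult:
    """PLINK-style greedy clumping of GWAS SNPs against an LD panel.

    Ties in p are broken by position then snp_id, making the block set
    invariant to input row order.
    """
    t = stats.table.set_index("snp_id")
    panel_ids = pd.Index(panel.variants["snp_id"])
    shared = panel_ids.intersection(t.index)
    if len(shared) == 0:
        raise ValueError("no SNPs shared between stats and panel")
    if len(shared) < len(t):
        logger.info("clump: %d stats SNPs absent from panel", len(t) - len(shared))

    panel_pos = panel_ids.get_indexer(shared)
    x = panel.dosage_float()[:, panel_pos]
    mean = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0)
    mono = sd == 0
    xs = np.nan_to_num((x - mean) / np.where(mono, np.inf, sd))
    n = panel.n_samples

    sub = t.loc[shared]
    p = sub["p_value"].to_numpy(dtype=float)
    chrom = panel.variants["chrom"].to_numpy()[panel_pos]
    pos = panel.variants["pos"].to_numpy(dtype=float)[panel_pos]
    ids = np.asarray(shared)
    pvals = dict(zip(ids, p))

    eligible = np.isfinite(p) & (p <= p_ceiling) & ~mono
    unassigned_always = [s for s, e in zip(ids, eligible) if not e]

    order = np.lexsort((ids, pos, p))
    order = order[eligible[order]]
    assigned = np.zeros(len(ids), dtype=bool)
    window_bp = window_kb * 1000.0
    blocks: list[ClumpBlock] = []
    for j in order:
        if assigned[j]:
            continue
        assigned[j] = True
        cand = np.flatnonzero(~assigned & eligible & (chrom == chrom[j]) &
                              (np.abs(pos - pos[j]) <= window_bp))
        members: list[str] = []
        if len(cand):
            r = xs[:, j] @ xs[:, cand] / n
            hit = cand[r * r >= r2_threshold - 1e-12]
            assigned[hit] = True
            hit = hit[np.lexsort((ids[hit], pos[hit]))]
            members = list(ids[hit])
        blocks.append(ClumpBlock(index_snp=str(ids[j]), members=members))
    return ClumpResult(blocks, r2_threshold, window_kb,
                       unassigned=sorted(unassigned_always), pvals=pvals)


def block_sample(clumps: ClumpResult, partition: Partition,
                 already_selected: set[str]) -> set[str]:
    """Draw at most one representative per LD block for a partition.

    For each block intersecting the partition whose members (index
    included) are not already represented in the cumulative model, the
    index variant is selected if it belongs to the partition; otherwise
    the partition member with the smallest GWAS p-value. Unassigned SNPs
    act as one-SNP blocks. Returns only the new selections; the caller
    merges them into the model set.
    """
    wanted = set(partition.snp_ids)
    out: set[str] = set()
    for b in clumps.blocks:
        block_snps = {b.index_snp, *b.members}
        if block_snps & already_selected:
            continue
        if b.index_snp in wanted:
            out.add(b.index_snp)
            continue
        hits = block_snps & wanted
        if hits:
            out.add(min(hits, key=lambda s: (clumps.pvals.get(s, np.inf), s)))
    for s in clumps.unassigned:
        if s in wanted and s not in already_selected:
            out.add(s)
    return out
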