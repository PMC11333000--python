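"""Greedy clumping against a brute-force reference, and block sampling."""

import numpy as np
import pytest

from titr.datamodel import Partition, SummaryStats, chi2_from_p
from titr.ldops import ClumpBlock, ClumpResult, block_sample, clump
from .conftest import make_genotypes, make_sumstats


def reference_clump(pvals, positions, r2, threshold, window_bp, ids):
    """Independent naive implementation of PLINK-style greedy clumping."""
    order = sorted(range(len(ids)), key=lambda i: (pvals[i], positions[i], ids[i]))
    assigned = set()
    blocks = []
    for i in order:
        if i in assigned:
            continue
        assigned.add(i)
        members = []
        for j in order:
            if j in assigned or abs(positions[j] - positions[i]) > window_bp:
                continue
            if r2[i, j] >= threshold - 1e-12:
                assigned.add(j)
                members.append(ids[j])
        blocks.append((ids[i], sorted(members)))
    return blocks


def _r2(geno):
    x = geno.dosages.astype(float)
    sd = x.std(axis=0)
    xs = (x - x.mean(axis=0)) / np.where(sd == 0, np.inf, sd)
    r = xs.T @ xs / len(x)
    return r * r


class TestClump:
    def test_hand_run_three_snp_example(self):
        # p = (1e-8, 1e-4, 0.3); r2(1,2) high, SNP 3 independent
        rng = np.random.default_rng(0)
        n = 400
        x1 = rng.integers(0, 3, size=n)
        noise = rng.uniform(size=n) < 0.15
        x2 = np.where(noise, rng.integers(0, 3, size=n), x1)
        x3 = rng.integers(0, 3, size=n)
        geno = make_genotypes(n, 3)
        geno.dosages = np.column_stack([x1, x2, x3]).astype(np.int8)
        t = make_sumstats(3).table
        t["p_value"] = [1e-8, 1e-4, 0.3]
        t["chi2"] = chi2_from_p(t["p_value"].to_numpy())
        stats = SummaryStats(t)
        result = clump(stats, geno, r2_threshold=0.2, window_kb=250)
        assert len(result.blocks) == 2
        assert result.blocks[0].index_snp == "rs0"
        assert result.blocks[0].members == ["rs1"]
        assert result.blocks[1].index_snp == "rs2"

    def test_threshold_one_makes_singletons(self):
        geno = make_genotypes(50, 10, seed=1)
        stats = make_sumstats(10, seed=1)
        result = clump(stats, geno, r2_threshold=1.0, window_kb=250)
        assert all(not b.members for b in result.blocks)
        assert len(result.blocks) == 10

    def test_row_order_invariance(self):
        geno = make_genotypes(60, 15, seed=2)
        stats = make_sumstats(15, seed=2)
        a = clump(stats, geno, window_kb=5)
        shuffled = SummaryStats(
            stats.table.sample(frac=1, random_state=0).reset_index(drop=True))
        b = clump(shuffled, geno, window_kb=5)
        assert [(x.index_snp, x.members) for x in a.blocks] == \
               [(x.index_snp, x.members) for x in b.blocks]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_reference_implementation(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(5, 50))
        geno = make_genotypes(80, m, seed=seed)
        # induce some LD by copying columns with noise
        for j in range(1, m):
            if rng.uniform() < 0.4:
                mask = rng.uniform(size=80) < 0.2
                geno.dosages[:, j] = np.where(
                    mask, geno.dosages[:, j], geno.dosages[:, j - 1])
        stats = make_sumstats(m, seed=seed)
        thr = float(rng.uniform(0.1, 0.9))
        wkb = float(rng.choice([3, 5, 250]))
        got = clump(stats, geno, r2_threshold=thr, window_kb=wkb)
        t = stats.table
        expect = reference_clump(t["p_value"].to_numpy(), t["pos"].to_numpy(),
                                 _r2(geno), thr, wkb * 1000,
                                 list(t["snp_id"]))
        assert [(b.index_snp, sorted(b.members)) for b in got.blocks] == expect

    def test_p_ceiling_moves_snps_to_unassigned(self):
        geno = make_genotypes(40, 10, seed=3)
        stats = make_sumstats(10, seed=3)
        ceiling = float(np.median(stats.table["p_value"]))
        result = clump(stats, geno, p_ceiling=ceiling)
        high = set(stats.table.loc[stats.table["p_value"] > ceiling, "snp_id"])
        assert set(result.unassigned) == high

    def test_empty_intersection_rejected(self):
        geno = make_genotypes(10, 5)
        stats = make_sumstats(5)
        stats.table["snp_id"] = [f"other{i}" for i in range(5)]
        with pytest.raises(ValueError, match="no SNPs shared"):
            clump(SummaryStats(stats.table), geno)


def _clumps():
    return ClumpResult(
        blocks=[ClumpBlock("A", ["B", "C"]), ClumpBlock("D", ["E"])],
        r2_threshold=0.2, window_kb=250, unassigned=["F"],
        pvals={"A": 1e-8, "B": 1e-5, "C": 1e-3, "D": 1e-6, "E": 0.5, "F": 0.9})


def _part(snps):
    return Partition("t", ("top", 0.01), frozenset(snps))


class TestBlockSample:
    def test_index_variant_preferred(self):
        assert block_sample(_clumps(), _part({"A", "B"}), set()) == {"A"}

    def test_best_member_when_index_absent(self):
        assert block_sample(_clumps(), _part({"B", "C"}), set()) == {"B"}

    def test_saturated_block_contributes_nothing(self):
        assert block_sample(_clumps(), _part({"A", "B"}), {"C"}) == set()

    def test_unassigned_snps_act_as_singleton_blocks(self):
        assert block_sample(_clumps(), _part({"F"}), set()) == {"F"}
        assert block_sample(_clumps(), _part({"F"}), {"F"}) == set()

    @pytest.mark.parametrize("seed", range(6))
    def test_never_two_snps_per_block_across_iterations(self, seed):
        rng = np.random.default_rng(seed)
        ids = [f"rs{i}" for i in range(40)]
        pvals = dict(zip(ids, rng.uniform(size=40)))
        blocks = []
        i = 0
        while i < 35:
            size = int(rng.integers(1, 5))
            members = ids[i + 1:i + size]
            blocks.append(ClumpBlock(ids[i], members))
            i += size
        clumps = ClumpResult(blocks, 0.2, 250, unassigned=ids[i:], pvals=pvals)
        block_of = clumps.block_of()
        selected: set[str] = set()
        for _ in range(6):
            part = _part(set(rng.choice(ids, size=10, replace=False)))
            new = block_sample(clumps, part, selected)
            selected |= new
            hit_blocks = [block_of[s] for s in selected]
            assert len(hit_blocks) == len(set(hit_blocks))
            n_blocks_in_part = len({block_of[s] for s in part.snp_ids})
            assert len(new) <= n_blocks_in_part
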