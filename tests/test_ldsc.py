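"""LD scores against brute force; stratified regression recovery,
calibration and the candidate-tissue gate."""

import numpy as np
import pandas as pd
import pytest

from titr.datamodel import MISSING, SummaryStats, p_from_chi2
from titr.ldsc import (CollinearityError, LdScoreTable, SldscFit,
                       compute_ld_scores, fit_sldsc, proportion_h2,
                       select_candidates)
from titr.simulate import simulate_chi2_from_ld_scores
from .conftest import make_genotypes


def brute_force_ld_scores(geno, annotations, window_kb):
    """Naive double loop over all in-window pairs (pairwise-complete r2)."""
    x = geno.dosage_float()
    m = geno.n_snps
    pos = geno.variants["pos"].to_numpy()
    chrom = geno.variants["chrom"].to_numpy()
    ell = np.zeros((m, annotations.shape[1]))
    for j in range(m):
        for k in range(m):
            if chrom[j] != chrom[k] or abs(pos[j] - pos[k]) > window_kb * 1000:
                continue
            both = np.isfinite(x[:, j]) & np.isfinite(x[:, k])
            a, b = x[both, j], x[both, k]
            if both.sum() < 2 or a.std() == 0 or b.std() == 0:
                continue
            r = np.corrcoef(a, b)[0, 1]
            ell[j] += r * r * annotations[k]
    return ell


def _stats_from_chi2(chi2, snp_ids, n_eff=1000.0):
    m = len(chi2)
    return SummaryStats(pd.DataFrame({
        "snp_id": snp_ids, "chrom": 1, "pos": (np.arange(m) + 1) * 1000,
        "effect_allele": "A", "other_allele": "G", "beta": np.nan,
        "p_value": p_from_chi2(chi2), "chi2": chi2, "n_eff": n_eff,
        "maf": 0.3,
    }))


class TestComputeLdScores:
    def test_single_snp_baseline_is_one(self):
        geno = make_genotypes(20, 1, seed=1)
        lds = compute_ld_scores(geno, np.ones((1, 1)), ["base"])
        assert lds.ell[0, 0] == pytest.approx(1.0)

    def test_two_identical_snps_give_two(self):
        geno = make_genotypes(30, 1, seed=2)
        geno2 = make_genotypes(30, 2, seed=2)
        geno2.dosages[:, 1] = geno2.dosages[:, 0]
        lds = compute_ld_scores(geno2, np.ones((2, 1)), ["base"])
        np.testing.assert_allclose(lds.ell[:, 0], 2.0, atol=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_with_annotations(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(5, 25))
        geno = make_genotypes(40, m, seed=seed)
        geno.dosages[rng.uniform(size=geno.dosages.shape) < 0.05] = MISSING
        annot = np.column_stack([np.ones(m), rng.uniform(size=m)])
        wkb = float(rng.choice([2, 5, 100]))
        lds = compute_ld_scores(geno, annot, ["base", "a"], window_kb=wkb)
        expect = brute_force_ld_scores(geno, annot, wkb)
        np.testing.assert_allclose(lds.ell, expect, atol=1e-10)

    def test_monomorphic_snp_contributes_zero(self):
        geno = make_genotypes(25, 3, seed=3)
        geno.dosages[:, 1] = 2
        lds = compute_ld_scores(geno, np.ones((3, 1)), ["base"])
        assert lds.ell[1, 0] == 0.0


class TestFitSldsc:
    def _lds(self, m=2000, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.uniform(size=m)
        annot = np.column_stack([np.ones(m), a])
        # varying local LD: each SNP tags `smear` neighbours on average,
        # whose annotation values sit near the track mean
        smear = rng.exponential(1.5, size=m)
        ell = np.column_stack([1.0 + smear, a + smear * a.mean()])
        return LdScoreTable(np.array([f"rs{i}" for i in range(m)]),
                            ["base", "a"], annot, ell, 1000.0,
                            chrom=np.ones(m, dtype=int),
                            pos=(np.arange(m) + 1) * 1000)

    def test_noise_free_recovery_exact(self):
        m = 1000
        lds = self._lds(m)
        n = 10000.0
        tau = 4e-5
        chi2 = 1.0 + n * tau * lds.ell[:, 0]
        stats = _stats_from_chi2(chi2, lds.snp_ids, n_eff=n)
        fit = fit_sldsc(stats, lds.columns(["base"]))
        assert fit.tau[0] == pytest.approx(tau, abs=1e-8 * tau)
        assert fit.intercept == pytest.approx(1.0, abs=1e-8)

    def test_zero_focal_tau_gives_zero_tau_star(self):
        # noise-free chi2 driven by the baseline only: the focal
        # annotation's tau is numerically zero and so is its tau*
        m = 1000
        lds = self._lds(m)
        n = 1000.0
        chi2 = 1.0 + n * 4e-4 * lds.ell[:, 0]
        fit = fit_sldsc(_stats_from_chi2(chi2, lds.snp_ids, n_eff=n), lds)
        assert abs(fit.tau[1]) < 1e-12
        assert abs(fit.tau_star[1]) < 1e-6

    def test_null_jackknife_ci_calibrated(self):
        covered = 0
        n_rep = 40
        for seed in range(n_rep):
            lds = self._lds(m=4000, seed=seed)
            stats = simulate_chi2_from_ld_scores(
                lds, np.array([1e-5, 0.0]), 5000.0, seed=100 + seed)
            fit = fit_sldsc(stats, lds)
            lo = fit.tau[1] - 1.96 * fit.tau_se[1]
            hi = fit.tau[1] + 1.96 * fit.tau_se[1]
            covered += lo <= 0.0 <= hi
        assert covered >= int(0.85 * n_rep)

    def test_collinear_annotations_named(self):
        m = 500
        lds = self._lds(m)
        dup = LdScoreTable(lds.snp_ids, ["base", "a", "a_copy"],
                           np.column_stack([lds.annotations, lds.annotations[:, 1]]),
                           np.column_stack([lds.ell, lds.ell[:, 1]]),
                           1000.0, lds.chrom, lds.pos)
        chi2 = np.ones(m)
        with pytest.raises(CollinearityError, match="a_copy"):
            fit_sldsc(_stats_from_chi2(chi2, lds.snp_ids), dup)

    def test_fit_invariant_to_snp_order(self):
        lds = self._lds(m=1000, seed=7)
        stats = simulate_chi2_from_ld_scores(lds, np.array([2e-5, 1e-5]),
                                             5000.0, seed=7)
        fit1 = fit_sldsc(stats, lds)
        perm = SummaryStats(stats.table.sample(frac=1, random_state=1)
                            .reset_index(drop=True))
        fit2 = fit_sldsc(perm, lds)
        np.testing.assert_allclose(fit1.tau, fit2.tau, rtol=1e-10)
        np.testing.assert_allclose(fit1.tau_se, fit2.tau_se, rtol=1e-10)


class TestProportionH2:
    def _fit_with_partition(self, member_frac=0.3, seed=0):
        m = 1000
        rng = np.random.default_rng(seed)
        member = (rng.uniform(size=m) < member_frac).astype(float)
        annot = np.column_stack([np.ones(m), member])
        smear = rng.exponential(1.5, size=m)
        ell = np.column_stack([1.0 + smear, member + smear * member.mean()])
        lds = LdScoreTable(np.array([f"rs{i}" for i in range(m)]),
                           ["base", "part"], annot, ell, 1000.0,
                           chrom=np.ones(m, dtype=int),
                           pos=(np.arange(m) + 1) * 1000)
        chi2 = 1.0 + 1000 * (4e-4 * ell[:, 0] + 4e-4 * ell[:, 1])
        fit = fit_sldsc(_stats_from_chi2(chi2, lds.snp_ids), lds)
        return fit, member

    def test_all_snps_partition_is_one(self):
        fit, _ = self._fit_with_partition()
        assert proportion_h2(fit, "base") == pytest.approx(1.0, abs=1e-6)

    def test_matches_hand_computation(self):
        fit, member = self._fit_with_partition()
        per_snp = fit.annotations @ fit.tau
        expect = per_snp[member == 1].sum() / per_snp.sum()
        assert proportion_h2(fit, "part") == pytest.approx(expect, rel=1e-9)

    def test_negative_total_h2_rejected(self):
        fit, _ = self._fit_with_partition()
        fit.h2_total = -0.1
        with pytest.raises(ValueError, match="h2_total"):
            proportion_h2(fit, "part")


def _hand_fit(tissue, tau_star, p):
    m = 100
    return SldscFit(
        annotation_names=["base", tissue],
        tau=np.array([1e-5, tau_star * 1e-5]),
        tau_se=np.array([1e-6, 1e-6]),
        tau_star=np.array([0.0, tau_star]),
        tau_star_se=np.array([1e-6, 0.1]),
        tau_star_p=np.array([1.0, p]),
        enrichment=np.array([1.0, 2.0]),
        enrichment_se=np.array([0.1, 0.1]),
        prop_h2=np.array([1.0, 0.2]),
        h2_total=0.4, intercept=1.0, n_blocks=20, n_snps=m,
        annotations=np.ones((m, 2)))


class TestSelectCandidates:
    def test_bonferroni_gate_on_hand_built_fits(self):
        fits = {
            "pancreas": _hand_fit("pancreas", 0.5, 5e-4),   # passes 0.05/51
            "liver": _hand_fit("liver", -0.5, 1e-9),        # wrong sign
            "brain": _hand_fit("brain", 0.5, 0.002),        # fails 0.05/51
        }
        assert select_candidates(fits, n_tissues=51) == ["pancreas"]

    def test_ordering_by_descending_tau_star(self):
        fits = {
            "a": _hand_fit("a", 0.3, 1e-6),
            "b": _hand_fit("b", 0.9, 1e-6),
            "c": _hand_fit("c", 0.6, 1e-6),
        }
        assert select_candidates(fits, n_tissues=51) == ["b", "c", "a"]

    def test_empty_selection_allowed(self):
        fits = {"a": _hand_fit("a", 0.3, 0.5)}
        assert select_candidates(fits, n_tissues=51) == []
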