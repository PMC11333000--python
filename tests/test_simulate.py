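"""The two-population study generator: LD contrast, enrichment, phenotypes,
marginal GWAS."""

import numpy as np
import pytest
from scipy import stats as sps

from titr.datamodel import MISSING
from titr import simulate
from titr.simulate import (SimConfig, choose_causal, simulate_annotations,
                           simulate_genotypes, simulate_gwas,
                           simulate_phenotype, simulate_study)
from .conftest import tiny_config


def _adjacent_r(geno):
    x = geno.dosages.astype(float)
    sd = x.std(axis=0)
    xs = (x - x.mean(axis=0)) / np.where(sd == 0, np.inf, sd)
    return np.array([(xs[:, j] * xs[:, j + 1]).mean()
                     for j in range(x.shape[1] - 1)])


class TestGenotypes:
    def test_fixed_seed_bitwise_identical(self):
        cfg = tiny_config(seed=5)
        a = simulate_genotypes(cfg, "train", n=50)
        b = simulate_genotypes(cfg, "train", n=50)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        assert a.sample_ids == b.sample_ids

    def test_rho_zero_gives_independent_adjacent_snps(self):
        cfg = tiny_config(block_rho_train=0.0, n_snps=300, n_blocks=30)
        geno = simulate_genotypes(cfg, "train", n=2000)
        assert np.mean(np.abs(_adjacent_r(geno))) < 0.05

    def test_train_ld_stronger_than_target(self):
        cfg = tiny_config(n_snps=300, n_blocks=30)
        train = simulate_genotypes(cfg, "train", n=2000)
        target = simulate_genotypes(cfg, "target", n=2000)
        r2_train = np.mean(_adjacent_r(train) ** 2)
        r2_target = np.mean(_adjacent_r(target) ** 2)
        assert r2_train > r2_target

    def test_shared_variant_metadata_across_populations(self):
        cfg = tiny_config()
        train = simulate_genotypes(cfg, "train", n=10)
        target = simulate_genotypes(cfg, "target", n=10)
        assert train.variants.equals(target.variants)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            simulate_genotypes(tiny_config(block_rho_train=1.0), "train", n=10)


class TestAnnotations:
    def test_no_enrichment_leaves_causal_uniform_over_bins(self):
        cfg = tiny_config(enrichment=1.0, n_snps=2000, n_blocks=200,
                          n_causal=400)
        causal, _ = choose_causal(cfg)
        tracks = simulate_annotations(cfg, set(causal))
        track = next(t for t in tracks if t.tissue_label == "adipose")
        mask = np.isin(track.snp_ids, causal)
        deciles = np.ceil(track.bin[mask] / 100).astype(int)
        counts = np.bincount(deciles, minlength=11)[1:]
        p = sps.chisquare(counts).pvalue
        assert p > 0.001

    def test_twenty_fold_top_percentile_occupancy(self):
        # 500 causal among 50,000 SNPs: expect about 500 * 0.2 = 100 in
        # the top-1% bin of each causal tissue
        cfg = SimConfig(seed=1, n_snps=50000, n_blocks=5000, n_causal=500,
                        enrichment=20.0, n_tissues=4,
                        causal_tissues=("adipose", "blood"))
        causal, _ = choose_causal(cfg)
        tracks = simulate_annotations(cfg, set(causal))
        for tissue in cfg.causal_tissues:
            track = next(t for t in tracks if t.tissue_label == tissue)
            mask = np.isin(track.snp_ids, causal)
            in_top = (track.bin[mask] <= 10).sum()
            assert 70 <= in_top <= 130  # 100 +- ~3 binomial sd

    def test_non_causal_tissue_independent_of_causal_status(self):
        pvals = []
        for seed in range(40):
            cfg = tiny_config(seed=seed, n_snps=1000, n_blocks=100,
                              n_causal=100)
            causal, _ = choose_causal(cfg)
            tracks = simulate_annotations(cfg, set(causal))
            track = next(t for t in tracks if t.tissue_label == "blood_vessel")
            mask = np.isin(track.snp_ids, causal)
            norm = simulate.quantile_normalize([track])[0].norm_score
            pvals.append(sps.ttest_ind(norm[mask], norm[~mask]).pvalue)
        # under independence p-values are uniform
        assert sps.kstest(pvals, "uniform").pvalue > 0.001

    def test_sub_unit_enrichment_rejected(self):
        cfg = tiny_config()
        causal, _ = choose_causal(cfg)
        cfg.enrichment = 0.5
        with pytest.raises(ValueError, match="enrichment"):
            simulate_annotations(cfg, set(causal))


class TestPhenotype:
    def test_zero_heritability_gives_no_genetic_slope(self):
        cfg = tiny_config(h2=0.0, n_train=500)
        geno = simulate_genotypes(cfg, "train", n=500)
        causal, betas = choose_causal(tiny_config(h2=0.5, n_train=500))
        y, _, _ = simulate_phenotype(geno, cfg, dict(zip(causal, betas)),
                                     with_covariates=False)
        g = geno.dosages[:, :5].astype(float) @ np.ones(5)
        slope = np.polyfit(g, y, 1)[0]
        assert abs(slope) < 0.05

    def test_variance_decomposition_matches_h2(self):
        cfg = tiny_config(h2=0.5, n_snps=600, n_blocks=60, n_causal=60)
        geno = simulate_genotypes(cfg, "train", n=4000)
        causal, betas = choose_causal(cfg)
        effects = dict(zip(causal, betas))
        y, _, _ = simulate_phenotype(geno, cfg, effects, with_covariates=False)
        sub = geno.subset_snps(causal)
        d = sub.dosages.astype(float)
        ds = (d - d.mean(0)) / d.std(0)
        g = ds @ np.array([effects[s] for s in causal])
        share = np.var(g * np.sqrt(cfg.h2) / g.std()) / np.var(y)
        assert 0.45 <= share <= 0.55

    def test_binary_control_case_ratio_exact(self):
        cfg = tiny_config(trait_type="binary", prevalence=0.15,
                          control_case_ratio=4.0)
        geno = simulate_genotypes(cfg, "train", n=800)
        causal, betas = choose_causal(cfg)
        y, cov, kept = simulate_phenotype(geno, cfg, dict(zip(causal, betas)))
        n_cases = int(y.sum())
        n_controls = len(y) - n_cases
        assert n_controls == int(np.floor(4.0)) * n_cases
        assert len(cov.frame) == len(y)

    def test_insufficient_controls_rejected(self):
        cfg = tiny_config(trait_type="binary", prevalence=0.5,
                          control_case_ratio=4.0)
        geno = simulate_genotypes(cfg, "train", n=300)
        causal, betas = choose_causal(cfg)
        with pytest.raises(ValueError, match="controls"):
            simulate_phenotype(geno, cfg, dict(zip(causal, betas)))


class TestGwas:
    def test_null_phenotype_p_uniform(self):
        cfg = tiny_config(n_snps=2000, n_blocks=2000, h2=0.0)
        geno = simulate_genotypes(cfg, "train", n=400)
        rng = np.random.default_rng(0)
        y = rng.normal(size=400)
        stats = simulate_gwas(geno, y)
        frac = (stats.table["p_value"] < 0.05).mean()
        assert 0.035 <= frac <= 0.065

    def test_single_causal_snp_attains_top_signal(self):
        hits = 0
        for seed in range(20):
            cfg = tiny_config(seed=seed, n_snps=200, n_blocks=200, h2=0.3,
                              n_causal=1)
            geno = simulate_genotypes(cfg, "train", n=5000)
            causal, betas = choose_causal(cfg)
            y, _, _ = simulate_phenotype(geno, cfg, dict(zip(causal, betas)),
                                         with_covariates=False)
            stats = simulate_gwas(geno, y)
            best = stats.table.loc[stats.table["p_value"].idxmin(), "snp_id"]
            hits += best == causal[0]
        assert hits >= 19

    def test_chi2_equals_squared_t(self):
        cfg = tiny_config(n_snps=100, n_blocks=10)
        geno = simulate_genotypes(cfg, "train", n=200)
        rng = np.random.default_rng(1)
        y = rng.normal(size=200)
        stats = simulate_gwas(geno, y)
        t = stats.table
        for j in [0, 13, 57]:
            snp = t.loc[j, "snp_id"]
            col = geno.dosages[:, list(geno.snp_ids).index(snp)].astype(float)
            res = sps.linregress(col, y)
            tstat = res.slope / res.stderr
            assert t.loc[j, "chi2"] == pytest.approx(tstat ** 2, abs=1e-10)

    def test_monomorphic_snp_dropped(self, caplog):
        cfg = tiny_config(n_snps=100, n_blocks=10)
        geno = simulate_genotypes(cfg, "train", n=120)
        geno.dosages[:, 7] = 2
        rng = np.random.default_rng(2)
        with caplog.at_level("INFO"):
            stats = simulate_gwas(geno, rng.normal(size=120))
        assert geno.snp_ids[7] not in set(stats.snp_ids)

    def test_missing_dosages_reduce_n_eff(self):
        cfg = tiny_config(n_snps=50, n_blocks=5)
        geno = simulate_genotypes(cfg, "train", n=100)
        geno.dosages[:10, 3] = MISSING
        rng = np.random.default_rng(3)
        stats = simulate_gwas(geno, rng.normal(size=100))
        t = stats.table.set_index("snp_id")
        assert t.loc[geno.snp_ids[3], "n_eff"] == 90


class TestStudyBundle:
    def test_full_determinism(self):
        cfg = tiny_config(seed=21)
        a = simulate_study(cfg)
        b = simulate_study(cfg)
        np.testing.assert_array_equal(a.train.dosages, b.train.dosages)
        np.testing.assert_array_equal(a.target_phenotype, b.target_phenotype)
        assert a.causal_snps == b.causal_snps
        np.testing.assert_array_equal(a.gwas_stats.table["chi2"],
                                      b.gwas_stats.table["chi2"])
        for ta, tb in zip(a.tracks, b.tracks):
            np.testing.assert_array_equal(ta.raw_score, tb.raw_score)

    def test_mean_chi2_matches_ld_score_expectation(self):
        # E[chi2] ~ 1 + N h2 l / M, the regression's own expectation
        cfg = tiny_config(seed=4, n_snps=1000, n_blocks=100, n_causal=200,
                          h2=0.5, n_gwas=2000)
        study = simulate_study(cfg)
        from titr.ldsc import compute_ld_scores
        lds = compute_ld_scores(study.panel, np.ones((1000, 1)), ["base"],
                                window_kb=50)
        expect = 1 + cfg.n_gwas * cfg.h2 * lds.ell[:, 0].mean() / cfg.n_snps
        observed = study.gwas_stats.table["chi2"].mean()
        assert observed == pytest.approx(expect, rel=0.15)
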