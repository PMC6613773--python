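"""Statistical and determinism properties of the study generator."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, multivariate_normal, norm

from polaris import synthetic_data as synth
from polaris.io_formats import MISSING
from polaris.qc import hard_call

from oracles import logistic_mle


def small_config(**kwargs):
    defaults = dict(
        seed=7,
        n_target=400,
        n_discovery=400,
        blocks=[synth.LDBlockSpec(5, 0.5)],
        fst=0.0,
        pc_liability=0.0,
        dosage_noise=0.0,
    )
    defaults.update(kwargs)
    return synth.SimConfig(**defaults)


class TestGenotypeSimulation:
    def test_determinism_bit_identical(self):
        cfg = small_config()
        a = synth.simulate_genotypes(cfg, "target")
        b = synth.simulate_genotypes(cfg, "target")
        np.testing.assert_array_equal(a.calls, b.calls)
        assert a.samples == b.samples

    def test_cohorts_are_independent(self):
        cfg = small_config(n_target=3000, n_discovery=3000,
                           blocks=[synth.LDBlockSpec(40, 0.0, (0.3, 0.5))])
        t = synth.simulate_genotypes(cfg, "target").calls.astype(float)
        d = synth.simulate_genotypes(cfg, "discovery").calls.astype(float)
        cross = [np.corrcoef(t[:, j], d[:, j])[0, 1] for j in range(40)]
        assert abs(np.mean(cross)) < 0.02

    def test_no_ld_when_rho_zero(self):
        cfg = small_config(n_target=10000, blocks=[synth.LDBlockSpec(6, 0.0, (0.5, 0.5))])
        g = synth.simulate_genotypes(cfg, "target").calls.astype(float)
        r = np.corrcoef(g, rowvar=False)
        off = r[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.03

    def test_adjacent_correlation_matches_thresholding_oracle(self):
        # haplotype-level allele correlation after dichotomizing a rho=0.9
        # bivariate normal at the MAF=0.3 quantile, computed from the exact
        # orthant probability (equals the 1e6-pair Monte-Carlo value to 4 dp)
        t = norm.ppf(0.3)
        p11 = multivariate_normal(cov=[[1, 0.9], [0.9, 1]]).cdf([t, t])
        expected = (p11 - 0.09) / (0.3 * 0.7)
        cfg = small_config(n_target=10000, blocks=[synth.LDBlockSpec(2, 0.9, (0.3, 0.3))])
        g = synth.simulate_genotypes(cfg, "target").calls.astype(float)
        observed = np.corrcoef(g[:, 0], g[:, 1])[0, 1]
        assert observed == pytest.approx(expected, abs=0.02)

    def test_maf_recovery_within_binomial_bound(self):
        cfg = small_config(n_target=5000, blocks=[synth.LDBlockSpec(30, 0.4, (0.1, 0.5))])
        gm = synth.simulate_genotypes(cfg, "target")
        freqs = synth._allele_frequencies(cfg)[0]
        realized = gm.calls.mean(axis=0) / 2.0
        bound = 3.0 * np.sqrt(freqs * (1 - freqs) / (2 * cfg.n_target))
        assert (np.abs(realized - freqs) <= bound).all()

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            synth.LDBlockSpec(3, 1.0)


class TestPhenotypes:
    def test_null_phenotype_independent_of_snps(self):
        cfg = small_config(n_target=1500, blocks=[synth.LDBlockSpec(1000, 0.0, (0.2, 0.5))])
        gm = synth.simulate_genotypes(cfg, "target")
        cov = synth.simulate_phenotypes(gm, cfg)
        y = cov.table["phenotype"].to_numpy(float)
        fits = synth.batched_single_snp_logistic(gm.calls.astype(float), y)
        pvals = fits.loc[fits["ok"], "p"]
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_case_fraction_respected(self):
        cfg = small_config(n_target=4000, case_fraction=0.25)
        gm = synth.simulate_genotypes(cfg, "target")
        cov = synth.simulate_phenotypes(gm, cfg)
        n_cases = int(cov.table["phenotype"].sum())
        assert 900 <= n_cases <= 1100

    def test_causal_snp_effect_recovered_within_3se(self):
        # one causal SNP at liability beta 0.5; the marginal log-odds of the
        # fitted logistic must be within 3 SE of the large-n Monte-Carlo
        # liability-to-logit conversion computed by an independent oracle
        beta_liab, maf, case_frac = 0.5, 0.4, 0.3
        oracle_rng = np.random.default_rng(99)
        n_oracle = 10**6
        g_o = oracle_rng.binomial(2, maf, n_oracle).astype(float)
        liab = beta_liab * g_o + oracle_rng.standard_normal(n_oracle)
        y_o = (liab > np.quantile(liab, 1 - case_frac)).astype(float)
        oracle_beta = logistic_mle(y_o, g_o[:, None])[1]

        cfg = small_config(
            seed=5, n_target=20000, case_fraction=case_frac,
            blocks=[synth.LDBlockSpec(1, 0.0, (maf, maf))],
            causal=[synth.CausalGeneSpec(0, 1, beta_liab)],
        )
        gm = synth.simulate_genotypes(cfg, "target")
        cov = synth.simulate_phenotypes(gm, cfg)
        fit = synth.batched_single_snp_logistic(
            gm.calls.astype(float), cov.table["phenotype"].to_numpy(float)
        )
        assert abs(fit.loc[0, "beta"] - oracle_beta) < 3 * fit.loc[0, "se"]


class TestDiscoverySummaryStats:
    def test_toy_table_beta_matches_likelihood_oracle(self):
        # printed genotype-by-status table: cases 10/40/50, controls 30/50/20
        g = np.repeat([0, 1, 2, 0, 1, 2], [10, 40, 50, 30, 50, 20]).astype(float)
        y = np.repeat([1, 1, 1, 0, 0, 0], [10, 40, 50, 30, 50, 20]).astype(float)
        fit = synth.batched_single_snp_logistic(g[:, None], y)
        oracle = logistic_mle(y, g[:, None])
        assert fit.loc[0, "beta"] == pytest.approx(oracle[1], abs=1e-6)
        assert fit.loc[0, "ok"]

    def test_null_scan_calibrated(self):
        cfg = small_config(n_discovery=1200, blocks=[synth.LDBlockSpec(2000, 0.0, (0.2, 0.5))])
        gm = synth.simulate_genotypes(cfg, "discovery")
        cov = synth.simulate_phenotypes(gm, cfg, "discovery")
        ss = synth.make_discovery_summary_stats(gm, cov)
        frac = (ss.table.loc[ss.table["ok"], "p"] < 0.05).mean()
        assert 0.036 <= frac <= 0.066  # 99% binomial band around 0.05, n=2000

    def test_monomorphic_snp_flagged_with_sentinels(self):
        gm = synth.simulate_genotypes(small_config(), "target")
        calls = gm.calls.copy()
        calls[:, 0] = 2
        y = np.tile([0, 1], gm.n_samples // 2)
        fits = synth.batched_single_snp_logistic(calls.astype(float), y)
        assert not fits.loc[0, "ok"]
        assert fits.loc[0, "beta"] == 0.0 and np.isinf(fits.loc[0, "se"])
        assert fits.loc[0, "p"] == 1.0

    def test_perfect_separation_flagged_not_fabricated(self):
        g = np.array([0, 0, 0, 1, 2, 2], float)[:, None]
        y = np.array([0, 0, 0, 1, 1, 1], float)
        fits = synth.batched_single_snp_logistic(g, y)
        assert not fits.loc[0, "ok"]
        assert np.isnan(fits.loc[0, "beta"]) and np.isinf(fits.loc[0, "se"])

    def test_effect_allele_is_a1(self):
        cfg = small_config()
        gm = synth.simulate_genotypes(cfg, "discovery")
        cov = synth.simulate_phenotypes(gm, cfg, "discovery")
        ss = synth.make_discovery_summary_stats(gm, cov)
        assert list(ss.table["effect_allele"]) == [v.a1 for v in gm.variants]


class TestImputationNoise:
    def test_zero_noise_unit_masses_and_info_one(self):
        gm = synth.simulate_genotypes(small_config(), "target")
        ds = synth.add_imputation_noise(gm, 0.0, seed=1)
        onehot = np.eye(3)[gm.calls]
        np.testing.assert_array_equal(ds.probs, onehot)
        assert all(v.info == 1.0 for v in ds.variants)

    def test_full_noise_kills_info(self):
        cfg = small_config(n_target=5000, blocks=[synth.LDBlockSpec(3, 0.0, (0.5, 0.5))])
        gm = synth.simulate_genotypes(cfg, "target")
        ds = synth.add_imputation_noise(gm, 1.0, seed=1)
        assert all(v.info < 0.2 for v in ds.variants)

    def test_hard_call_inverts_zero_noise(self):
        gm = synth.simulate_genotypes(small_config(), "target")
        ds = synth.add_imputation_noise(gm, 0.0, seed=1)
        back = hard_call(ds, 0.9)
        np.testing.assert_array_equal(back.calls, gm.calls)

    def test_noise_level_monotone_in_info(self):
        cfg = small_config(n_target=3000, blocks=[synth.LDBlockSpec(4, 0.0, (0.3, 0.5))])
        gm = synth.simulate_genotypes(cfg, "target")
        infos = [
            np.mean([v.info for v in synth.add_imputation_noise(gm, eta, seed=1).variants])
            for eta in (0.0, 0.3, 0.7, 1.0)
        ]
        assert infos == sorted(infos, reverse=True)


class TestGeneModels:
    def test_overlap_gene_shares_snps(self):
        cfg = small_config(include_overlap_gene=True)
        genes, _ = synth.make_gene_models(cfg)
        t = genes.table.set_index("gene_id")
        g0, ovl = t.loc["GENE0001"], t.loc["GENE_OVL"]
        assert ovl.start <= g0.end and g0.start <= ovl.end  # genomic overlap

    def test_minus_strand_and_filterable_genes_present(self):
        cfg = small_config(blocks=[synth.LDBlockSpec(5, 0.5)] * 3)
        genes, _ = synth.make_gene_models(cfg)
        assert (genes.table["strand"] == "-").any()
        assert (genes.table["biotype"] != "protein_coding").any()
        assert (genes.table["status"] != "KNOWN").any()

    def test_truth_table_marks_exactly_the_causal_specs(self):
        cfg = small_config(
            blocks=[synth.LDBlockSpec(5, 0.5)] * 4,
            causal=[synth.CausalGeneSpec(2, 2, 0.3)],
        )
        _, truth = synth.make_gene_models(cfg)
        causal = set(truth.loc[truth["causal"], "gene_id"])
        assert causal == {"GENE0003"}
        snps = truth.set_index("gene_id").loc["GENE0003", "causal_snps"].split(",")
        assert len(snps) == 2

    def test_study_bundle_determinism(self):
        cfg = small_config(n_target=100, n_discovery=100, dosage_noise=0.1)
        a = synth.simulate_study(cfg)
        b = synth.simulate_study(cfg)
        np.testing.assert_array_equal(a.target_truth.calls, b.target_truth.calls)
        np.testing.assert_array_equal(a.target_dosages.probs, b.target_dosages.probs)
        pd.testing.assert_frame_equal(a.summary_stats.table, b.summary_stats.table)
        pd.testing.assert_frame_equal(a.target_covariates.table, b.target_covariates.table)
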