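"""LD scores, partitioned regression, jackknife, enrichment, conditioning."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_correlation
from genarch import ldsc
from genarch import simulate as sim
from genarch.containers import AnnotationMatrix, LDMatrix, SumStats
from genarch.errors import ArgumentError, IntegrityError, NumericError


def make_annot(values: dict, n: int) -> AnnotationMatrix:
    snps = pd.DataFrame({"SNP": [f"s{i}" for i in range(n)], "CHR": "1",
                         "BP": np.arange(1, n + 1)})
    return AnnotationMatrix(snps, pd.DataFrame(values))


def make_sumstats(chi2, n_gwas, m):
    table = pd.DataFrame({
        "SNP": [f"s{i}" for i in range(m)], "CHR": "1",
        "BP": np.arange(1, m + 1), "A1": "A", "A2": "G",
        "Z": np.sqrt(chi2), "N": float(n_gwas)})
    return SumStats(table)


class TestLdScores:
    def test_identity_ld_all_ones_annotation(self):
        annot = make_annot({"base": np.ones(6)}, 6)
        scores = ldsc.ld_scores(np.eye(6), annot)
        assert np.allclose(scores.scores["base"], 1.0)

    def test_identity_ld_returns_annotation(self, rng):
        a = rng.uniform(0, 1, 6)
        annot = make_annot({"c": a}, 6)
        scores = ldsc.ld_scores(np.eye(6), annot)
        assert np.allclose(scores.scores["c"], a)

    def test_matches_double_loop_oracle(self, rng):
        m = 10
        r = random_correlation(rng, m)
        a1 = rng.integers(0, 2, m).astype(float)
        a2 = rng.uniform(0, 1, m)
        annot = make_annot({"bin": a1, "cont": a2}, m)
        scores = ldsc.ld_scores(r, annot)
        for name, a in (("bin", a1), ("cont", a2)):
            for j in range(m):
                expected = sum(a[k] * r[j, k] ** 2 for k in range(m))
                assert scores.scores[name][j] == pytest.approx(expected,
                                                               abs=1e-12)

    def test_literal_unsquared_mode(self, rng):
        m = 6
        r = random_correlation(rng, m)
        a = rng.uniform(0, 1, m)
        annot = make_annot({"c": a}, m)
        scores = ldsc.ld_scores(r, annot, squared=False)
        assert np.allclose(scores.scores["c"], r @ a, atol=1e-12)

    def test_bias_adjustment_direction(self, rng):
        m = 6
        r = random_correlation(rng, m)
        annot = make_annot({"base": np.ones(m)}, m)
        raw = ldsc.ld_scores(r, annot).scores["base"]
        adj = ldsc.ld_scores(r, annot, n_ref=100).scores["base"]
        assert np.all(adj <= raw)

    def test_index_mismatch_error(self, rng):
        annot = make_annot({"base": np.ones(4)}, 4)
        with pytest.raises(IntegrityError):
            ldsc.ld_scores(np.eye(5), annot)


class TestBlockJackknife:
    def test_identical_blocks_zero_se(self):
        data = np.tile([1.0, 2.0], 10)
        res = ldsc.block_jackknife(lambda idx: data[idx].mean(), 20,
                                   n_blocks=10)
        assert res.se[0] == pytest.approx(0.0, abs=1e-14)

    def test_mean_matches_closed_form_se(self, rng):
        x = rng.normal(size=40)
        res = ldsc.block_jackknife(lambda idx: x[idx].mean(), 40, n_blocks=40)
        closed = x.std(ddof=1) / np.sqrt(40)
        assert res.se[0] == pytest.approx(closed, abs=1e-10)

    def test_equal_blocks_match_block_mean_se(self, rng):
        x = rng.normal(size=60)
        res = ldsc.block_jackknife(lambda idx: x[idx].mean(), 60, n_blocks=12)
        block_means = x.reshape(12, 5).mean(axis=1)
        closed = block_means.std(ddof=1) / np.sqrt(12)
        assert res.se[0] == pytest.approx(closed, abs=1e-10)

    def test_too_few_blocks(self):
        with pytest.raises(ArgumentError):
            ldsc.block_jackknife(lambda idx: 0.0, 10, n_blocks=1)


class TestStandardizeTau:
    def test_direct_formula(self):
        assert ldsc.standardize_tau(2e-4, 1000, 0.2, 0.4) == pytest.approx(0.1)

    def test_zero_tau(self):
        assert ldsc.standardize_tau(0.0, 1000, 0.2, 0.4) == 0.0

    def test_scaling_in_sd(self, rng):
        tau = rng.normal(size=5)
        sd = rng.uniform(0.05, 0.5, 5)
        a = ldsc.standardize_tau(tau, 500, sd, 0.3)
        b = ldsc.standardize_tau(tau, 500, 2 * sd, 0.3)
        assert np.allclose(b, 2 * a)

    def test_invalid_h2(self):
        with pytest.raises(ArgumentError):
            ldsc.standardize_tau(1e-4, 100, 0.1, 0.0)


class TestRegressPartitioned:
    @pytest.mark.parametrize("weights_mode", ["ols", "ldsc"])
    def test_noiseless_exact_recovery(self, rng, weights_mode):
        m, n_gwas = 120, 5000
        r = random_correlation(rng, m)
        a_bin = (rng.random(m) < 0.3).astype(float)
        annot = make_annot({"base": np.ones(m), "extra": a_bin}, m)
        scores = ldsc.ld_scores(r, annot)
        tau = np.array([2e-5, 5e-5])
        chi2 = n_gwas * scores.scores.to_numpy() @ tau + 1.0
        est = ldsc.regress_partitioned(make_sumstats(chi2, n_gwas, m), scores,
                                       weights_mode=weights_mode, n_blocks=20)
        assert np.max(np.abs(est.tau - tau)) < 1e-8
        assert est.intercept == pytest.approx(1.0, abs=1e-8)
        assert est.h2 == pytest.approx(float(tau @ annot.m_annot()), rel=1e-6)

    def test_snp_order_invariance(self, rng):
        panel = sim.simulate_ld_panel(800, 120, block_size=6, rho=(0, 0.9),
                                      seed=31)
        annot = sim.baseline_annotation(panel)
        scores = ldsc.ld_scores(panel.ld_matrix(), annot, n_ref=800)
        ss, _ = sim.simulate_gwas(panel, annot, {"base": 0.3 / 120}, seed=32)
        est = ldsc.regress_partitioned(ss, scores, n_blocks=10)
        perm = rng.permutation(120)
        scores_p = ldsc.LDScoreMatrix(
            [scores.snps[i] for i in perm], scores.scores.iloc[perm],
            scores.m_annot, scores.sd_annot, scores.m_ref)
        est_p = ldsc.regress_partitioned(ss, scores_p, n_blocks=10)
        assert est_p.tau[0] == pytest.approx(est.tau[0], rel=1e-10)
        assert est_p.intercept == pytest.approx(est.intercept, rel=1e-10)

    def test_rank_deficiency_names_columns(self):
        m = 30
        a = np.ones(m)
        annot = make_annot({"base": a, "copy": a}, m)
        scores = ldsc.ld_scores(np.eye(m), annot)
        with pytest.raises(NumericError, match="collinear"):
            ldsc.regress_partitioned(make_sumstats(np.ones(m), 100, m),
                                     scores, n_blocks=5)

    def test_confounding_recovered_in_intercept(self):
        panel = sim.simulate_ld_panel(2500, 600, block_size=12, rho=(0, 0.9),
                                      seed=33)
        annot = sim.baseline_annotation(panel)
        scores = ldsc.ld_scores(panel.ld_matrix(), annot, n_ref=2500)
        ints, taus, tau_ses = [], [], []
        for rep in range(8):
            ss, _ = sim.simulate_gwas(panel, annot, {"base": 0.0},
                                      intercept_inflation=0.5, seed=40 + rep)
            est = ldsc.regress_partitioned(ss, scores, n_blocks=100)
            ints.append(est.intercept)
            taus.append(est.tau[0])
            tau_ses.append(est.tau_se[0])
        # intercept absorbs the uniform inflation: 1 + Nb = 1.5
        assert abs(np.mean(ints) - 1.5) < 0.2
        # tau stays at zero within its jackknife uncertainty
        assert abs(np.mean(taus)) < 3 * np.mean(tau_ses) / np.sqrt(8)


class TestEnrichment:
    def make_fit(self, rng, values, tau_true, n_gwas=4000, m=None):
        m = m or len(next(iter(values.values())))
        annot = make_annot(values, m)
        scores = ldsc.ld_scores(random_correlation(rng, m), annot)
        chi2 = n_gwas * scores.scores.to_numpy() @ np.asarray(tau_true) + 1.0
        est = ldsc.regress_partitioned(make_sumstats(chi2, n_gwas, m), scores,
                                       weights_mode="ols", n_blocks=10)
        return est, annot

    def test_all_snps_annotation_enrichment_one(self, rng):
        est, annot = self.make_fit(rng, {"base": np.ones(50)}, [1e-4])
        enr = ldsc.enrichment(est, annot)
        assert enr["enrichment"][0] == pytest.approx(1.0, rel=1e-9)

    def test_disjoint_partition_conservation(self, rng):
        m = 60
        a1 = np.zeros(m); a1[:20] = 1
        a2 = np.zeros(m); a2[20:] = 1
        est, annot = self.make_fit(rng, {"left": a1, "right": a2},
                                   [3e-4, 1e-5], m=m)
        enr = ldsc.enrichment(est, annot)
        total = float((enr["prop_snps"] * enr["enrichment"]).sum())
        assert total == pytest.approx(1.0, rel=1e-8)

    def test_concentrated_signal_enrichment_ten(self, rng):
        # all causal variance on 10% of SNPs -> enrichment converges to 10.
        # Per-replicate enrichment is a ratio whose denominator (h2-hat) is
        # noisy, so convergence is assessed on the replicate-averaged fit.
        from dataclasses import replace
        panel = sim.simulate_ld_panel(5000, 400, block_size=8, rho=(0, 0.8),
                                      seed=50)
        mask = np.zeros(400); mask[::10] = 1.0
        annot = sim.baseline_annotation(panel, extra={"hot": mask})
        scores = ldsc.ld_scores(panel.ld_matrix(), annot, n_ref=5000)
        fits = []
        for rep in range(30):
            ss, _ = sim.simulate_gwas(panel, annot,
                                      {"base": 0.0, "hot": 0.5 / 40},
                                      seed=60 + rep)
            fits.append(ldsc.regress_partitioned(ss, scores, n_blocks=50))
        mean_fit = replace(
            fits[-1], tau=np.mean([f.tau for f in fits], axis=0),
            tau_deletes=np.mean([f.tau_deletes for f in fits], axis=0))
        enr = ldsc.enrichment(mean_fit, annot)
        hot = float(enr.set_index("annotation").loc["hot", "enrichment"])
        assert abs(hot - 10.0) < 2.5

    def test_continuous_annotation_unsupported(self, rng):
        m = 30
        est, annot = self.make_fit(rng, {"base": np.ones(m)}, [1e-4])
        cont = make_annot({"base": np.linspace(0, 1, m)}, m)
        with pytest.raises(ArgumentError, match="tau"):
            ldsc.enrichment(est, cont)


class TestConditionalModel:
    @pytest.fixture(scope="class")
    def cond_setup(self):
        panel = sim.simulate_ld_panel(2500, 500, block_size=10, rho=(0, 0.9),
                                      seed=70)
        rng = np.random.default_rng(71)
        focus = (rng.random(500) < 0.25).astype(float)
        annot = sim.baseline_annotation(panel, extra={"focus": focus})
        scores = ldsc.ld_scores(panel.ld_matrix(), annot, n_ref=2500)
        return panel, annot, scores

    def test_focus_in_baseline_rejected(self, cond_setup):
        _, _, scores = cond_setup
        ss = make_sumstats(np.ones(500), 100, 500)
        with pytest.raises(ArgumentError):
            ldsc.conditional_model(ss, scores, "base", ["base", "focus"])

    def test_power_for_true_focus_signal(self, cond_setup):
        panel, annot, scores = cond_setup
        detected = 0
        reps = 25
        for rep in range(reps):
            ss, _ = sim.simulate_gwas(
                panel, annot, {"base": 0.1 / 500, "focus": 0.5 / 125},
                seed=80 + rep)
            row = ldsc.conditional_model(ss, scores, "focus", ["base"],
                                         n_blocks=50)
            detected += row["p_one_sided"] < 0.05
        assert detected / reps >= 0.8

    def test_null_focus_p_uniform(self, cond_setup):
        panel, annot, scores = cond_setup
        from scipy import stats
        ps = []
        for rep in range(40):
            ss, _ = sim.simulate_gwas(panel, annot,
                                      {"base": 0.3 / 500, "focus": 0.0},
                                      seed=200 + rep)
            row = ldsc.conditional_model(ss, scores, "focus", ["base"],
                                         n_blocks=50)
            ps.append(row["p_one_sided"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestMeanTauStar:
    def test_single_annotation_identity(self, rng):
        star = 0.4
        deletes = rng.normal(0.4, 0.05, size=20)
        mean, se = ldsc.mean_tau_star([(star, deletes)])
        assert mean == pytest.approx(star)
        b = 20
        exp_se = np.sqrt((b - 1) / b * ((deletes - deletes.mean())**2).sum())
        assert se == pytest.approx(exp_se)

    def test_identical_columns_equal_single(self, rng):
        deletes = rng.normal(0.4, 0.05, size=20)
        one = ldsc.mean_tau_star([(0.4, deletes)])
        three = ldsc.mean_tau_star([(0.4, deletes)] * 3)
        assert three == pytest.approx(one)


class TestAdjustPvalues:
    def test_bonferroni_denominator(self):
        p = np.array([4e-6, 6e-6, 0.5])
        flags = ldsc.adjust_pvalues(p, method="bonferroni", n_tests=10_000)
        assert list(flags) == [True, False, False]

    def test_bh_matches_step_up_reference(self, rng):
        p = rng.uniform(size=40)
        flags = ldsc.adjust_pvalues(p, method="bh", alpha=0.05)
        # independent step-up implementation
        order = np.argsort(p)
        n = len(p)
        thresh = 0.05 * (np.arange(1, n + 1)) / n
        passed = np.where(p[order] <= thresh)[0]
        ref = np.zeros(n, bool)
        if passed.size:
            ref[order[:passed.max() + 1]] = True
        assert np.array_equal(flags, ref)
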