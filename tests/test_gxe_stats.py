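"""Interaction modelling, sign tests, attenuation and Cochran's Q."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from grscore import (AssocResult, SimulationConfig, attenuation_pct,
                     cochran_q, compute_grs, count_consistent,
                     covariate_design, fit_interaction, sign_binomial_test,
                     simulate_cohort)

# directionally-consistent counts among the 28 SNPs for the three
# fat-percentage traits (positive printed betas; near-zero negatives count
# against), frozen from the study's reported per-SNP effect signs
FAT_TRAIT_CONSISTENT = {"body": 22, "trunk": 21, "leg": 18}


def binomial_tail_oracle(k, n):
    return float(sum(Fraction(math.comb(n, j), 2 ** n)
                     for j in range(k, n + 1)))


class TestSignBinomialTest:
    @pytest.mark.parametrize("k,n,printed,tol", [
        # tolerance = half a unit in the last printed digit
        (26, 28, 1.52e-6, 0.005e-6),  # BMI direction consistency
        (22, 28, 0.002, 5e-4),        # body fat (1 s.f.)
        (21, 28, 0.006, 5e-4),        # trunk fat (1 s.f.)
        (18, 28, 0.092, 5e-4),        # leg fat
    ])
    def test_reproduces_reported_tails(self, k, n, printed, tol):
        p = sign_binomial_test(k, n).p_one_sided
        assert p == pytest.approx(printed, abs=tol)

    def test_all_consistent(self):
        assert sign_binomial_test(28, 28).p_one_sided == pytest.approx(2.0 ** -28)

    @pytest.mark.parametrize("k", [0, 7, 14, 21, 28])
    def test_matches_enumeration_oracle(self, k):
        assert sign_binomial_test(k, 28).p_one_sided == pytest.approx(
            binomial_tail_oracle(k, 28), abs=1e-15)

    @given(st.integers(min_value=1, max_value=50))
    def test_strictly_decreasing_in_k(self, n):
        # strict monotonicity holds exactly in rational arithmetic; above
        # n ≈ 50 the top tails collide at double-precision resolution, so
        # the property is asserted within the exactly-representable range
        ps = [sign_binomial_test(k, n).p_one_sided for k in range(n + 1)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sign_binomial_test(5, 4)
        with pytest.raises(ValueError):
            sign_binomial_test(0, 0)


def _assoc(predictor, beta):
    return AssocResult(predictor=predictor, trait="bmi", beta=beta, se=0.1,
                       p=0.5, n=100, covariates=())


class TestCountConsistent:
    def test_counts_and_zero_handling(self):
        results = [_assoc("rs1", 0.2), _assoc("rs2", -0.1),
                   _assoc("rs3", 0.0), _assoc("rs4", 0.05)]
        refs = {"rs1": 1, "rs2": 1, "rs3": 1, "rs4": -1}
        cc = count_consistent(results, refs)
        assert (cc.n_consistent, cc.n_total, cc.n_zero) == (1, 4, 1)

    def test_fat_trait_sign_tests_chain(self):
        # the frozen consistent-counts reproduce the reported binomial p's
        for trait, k in FAT_TRAIT_CONSISTENT.items():
            p = sign_binomial_test(k, 28).p_one_sided
            expected = {"body": 0.002, "trunk": 0.006, "leg": 0.092}[trait]
            assert p == pytest.approx(expected, abs=5e-4)

    def test_missing_reference_is_error(self):
        with pytest.raises(ValueError, match="rs9"):
            count_consistent([_assoc("rs9", 0.1)], {})


class TestAttenuation:
    def test_reported_sixty_percent(self):
        assert attenuation_pct(0.20, 0.08) == pytest.approx(60.0)

    def test_no_change_and_aggravation(self):
        assert attenuation_pct(0.37, 0.37) == 0.0
        assert attenuation_pct(0.10, 0.20) == pytest.approx(-100.0)

    def test_zero_low_effect_undefined(self):
        with pytest.raises(ValueError):
            attenuation_pct(0.0, 0.1)


class TestCochranQ:
    def test_identical_estimates(self):
        res = cochran_q(0.11, 0.02, 0.11, 0.02)
        assert res.q_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # w = 100 each, pooled beta 0, Q = 100·1 + 100·1 = 200
        res = cochran_q(1.0, 0.1, -1.0, 0.1)
        assert res.q_statistic == pytest.approx(200.0, rel=1e-12)
        assert res.df == 1
        assert res.i_squared == pytest.approx((200 - 1) / 200)

    def test_location_invariance_and_symmetry(self):
        a = cochran_q(0.17, 0.03, 0.11, 0.02)
        b = cochran_q(1.17, 0.03, 1.11, 0.02)
        c = cochran_q(0.11, 0.02, 0.17, 0.03)
        assert a.q_statistic == pytest.approx(b.q_statistic, rel=1e-10)
        assert a.p == pytest.approx(c.p, rel=1e-10)

    def test_invalid_se(self):
        with pytest.raises(ValueError):
            cochran_q(0.1, 0.0, 0.2, 0.1)


class TestFitInteraction:
    def test_recovers_generating_delta(self, panel):
        # cohorts generated at the study's interaction effect: the mean
        # estimate over seeds is within Monte-Carlo error of the truth
        est = []
        for seed in range(60):
            c = simulate_cohort(SimulationConfig(
                n_individuals=2894, panel=panel, grs_beta=0.11,
                interaction_beta=-0.06, seed=9000 + seed))
            grs = compute_grs(c.genotypes, panel)
            cov = covariate_design(c.phenotypes, "bmi-set")
            res = fit_interaction(c.phenotypes.data["bmi"], grs.score,
                                  c.phenotypes.pa_code, cov)
            est.append(res.beta_interaction)
        se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert np.mean(est) == pytest.approx(-0.06, abs=3 * se)

    def test_stratum_betas_monotone_in_expectation(self, panel):
        lows, mods, highs = [], [], []
        for seed in range(60):
            c = simulate_cohort(SimulationConfig(
                n_individuals=2894, panel=panel, grs_beta=0.2,
                interaction_beta=-0.08, seed=11000 + seed))
            grs = compute_grs(c.genotypes, panel)
            res = fit_interaction(c.phenotypes.data["bmi"], grs.score,
                                  c.phenotypes.pa_code)
            lows.append(res.stratum["low"].beta)
            mods.append(res.stratum["moderate"].beta)
            highs.append(res.stratum["high"].beta)
        assert np.mean(lows) > np.mean(mods) > np.mean(highs)

    def test_null_interaction_p_uniform(self, small_panel):
        pvals = []
        for seed in range(300):
            c = simulate_cohort(SimulationConfig(
                n_individuals=250, panel=small_panel, seed=13000 + seed))
            score = c.genotypes.dosage.sum(axis=1)
            res = fit_interaction(c.phenotypes.data["bmi"], score,
                                  c.phenotypes.pa_code)
            pvals.append(res.p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_permutation_null_rejection_rate(self, panel, rng):
        # shuffling PA breaks any interaction: rejection at alpha stays near
        # alpha across permutations of one effect-bearing cohort
        c = simulate_cohort(SimulationConfig(
            n_individuals=1000, panel=panel, grs_beta=0.2,
            interaction_beta=-0.1, seed=77))
        score = c.genotypes.dosage.sum(axis=1)
        bmi = c.phenotypes.data["bmi"].to_numpy()
        pa = c.phenotypes.pa_code.to_numpy()
        rejections = 0
        n_perm = 400
        for _ in range(n_perm):
            res = fit_interaction(bmi, score, rng.permutation(pa))
            rejections += res.p < 0.05
        rate = rejections / n_perm
        se = np.sqrt(0.05 * 0.95 / n_perm)
        assert abs(rate - 0.05) < 3.5 * se

    def test_stratum_ns_sum_to_n(self, null_cohort):
        score = null_cohort.genotypes.dosage.sum(axis=1)
        res = fit_interaction(null_cohort.phenotypes.data["bmi"], score,
                              null_cohort.phenotypes.pa_code)
        assert sum(s.n for s in res.stratum.values()) == res.n

    def test_attenuation_property(self):
        from grscore.gxe_stats import InteractionResult, StratumEffect
        res = InteractionResult(
            predictor="GRS", trait="bmi", beta_interaction=-0.06, se=0.03,
            p=0.022, n=2894, covariates=(),
            stratum={"low": StratumEffect(0.20, 0.08, 0.009, 219),
                     "moderate": StratumEffect(0.12, 0.03, 0.0003, 1226),
                     "high": StratumEffect(0.08, 0.03, 0.004, 1449)})
        assert res.attenuation == pytest.approx(60.0)

    def test_sensitivity_subset_exclusion(self, panel):
        # dropping designated SNPs from the score only changes bookkeeping
        c = simulate_cohort(SimulationConfig(
            n_individuals=400, panel=panel, grs_beta=0.1, seed=55))
        drop = {"rs574367", "rs9939609", "rs11127485"}
        keep = [r.rsid for r in panel if r.rsid not in drop]
        reduced = compute_grs(c.genotypes, panel, keep)
        assert reduced.subset_name == "custom"
        assert set(reduced.snps_used) == set(keep)
        res = fit_interaction(c.phenotypes.data["bmi"], reduced.score,
                              c.phenotypes.pa_code)
        assert np.isfinite(res.beta_interaction)
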