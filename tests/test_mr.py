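"""MR estimators: Wald ratio, IVW random effects, Egger intercept, BH."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from targetmr import bh_adjust, egger_intercept, ivw_random_effects, run_mr_gene, wald_ratio
from targetmr.records import HarmonizedPair


def pair(b_exp, b_out, se_out=0.05, se_exp=0.01, snp="rs1"):
    return HarmonizedPair(snp, "A", "G", b_exp, se_exp, b_out, se_out, 0.3, 0.3, "none")


class TestWaldRatio:
    def test_arithmetic(self):
        beta, se, p = wald_ratio(pair(0.5, 0.2, se_out=0.05))
        assert beta == pytest.approx(0.4)
        assert se == pytest.approx(0.1)
        assert np.exp(beta) == pytest.approx(1.4918, abs=1e-4)

    def test_null_outcome(self):
        beta, _, p = wald_ratio(pair(0.5, 0.0))
        assert beta == 0.0 and p == 1.0

    def test_negative_exposure_effect(self):
        beta, se, _ = wald_ratio(pair(-0.5, 0.2, se_out=0.05))
        assert beta == pytest.approx(-0.4)
        assert se == pytest.approx(0.1)

    def test_zero_exposure_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(pair(0.0, 0.2))


class TestIVW:
    def test_equal_ratios_q_zero(self):
        # ratios both 0.4 with ratio se 0.1 and 0.2
        pairs = [pair(1.0, 0.4, se_out=0.1), pair(1.0, 0.4, se_out=0.2)]
        beta, se, _, q, q_df, _ = ivw_random_effects(pairs)
        assert beta == pytest.approx(0.4)
        assert q == pytest.approx(0.0, abs=1e-24)
        assert se == pytest.approx(1 / np.sqrt(125))

    def test_heterogeneous_ratios(self):
        pairs = [pair(1.0, 0.3, se_out=0.1), pair(1.0, 0.5, se_out=0.1)]
        beta, se, _, q, q_df, q_p = ivw_random_effects(pairs)
        assert beta == pytest.approx(0.4)
        assert q == pytest.approx(2.0)
        assert q_df == 1
        assert q_p == pytest.approx(0.1573, abs=1e-4)
        # multiplicative RE scales the fixed se 1/sqrt(200) by sqrt(Q/df)
        assert se == pytest.approx(np.sqrt(2.0) / np.sqrt(200.0))

    def test_matches_wls_through_origin(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            k = int(rng.integers(2, 9))
            b_exp = rng.uniform(0.1, 0.8, k) * rng.choice([-1, 1], k)
            b_out = rng.normal(0.05, 0.1, k)
            se_out = rng.uniform(0.01, 0.2, k)
            pairs = [pair(b_exp[i], b_out[i], se_out=se_out[i], snp=f"s{i}")
                     for i in range(k)]
            beta, se, _, q, _, _ = ivw_random_effects(pairs)
            fit = sm.WLS(b_out, b_exp[:, None], weights=1 / se_out**2).fit()
            assert beta == pytest.approx(float(fit.params[0]), abs=1e-10)
            se_fe = 1 / np.sqrt(np.sum((b_exp / se_out) ** 2))
            assert se >= se_fe - 1e-15

    def test_additive_flavor_runs_and_inflates(self):
        pairs = [pair(1.0, r, se_out=0.05, snp=f"s{i}")
                 for i, r in enumerate([0.1, 0.5, 0.9])]
        b_mul, se_mul, *_ = ivw_random_effects(pairs, flavor="multiplicative")
        b_add, se_add, *_ = ivw_random_effects(pairs, flavor="additive")
        se_fe = 0.05 / np.sqrt(3)
        assert se_add > se_fe and se_mul > se_fe

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            ivw_random_effects([pair(1.0, 0.4)])


class TestEgger:
    def test_exact_line_through_origin(self):
        pairs = [pair(x, 0.4 * x, snp=f"s{i}") for i, x in enumerate([0.2, 0.5, 0.9])]
        intercept, _, _ = egger_intercept(pairs)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_line_with_intercept(self):
        pairs = [pair(x, 0.1 + 0.4 * x, snp=f"s{i}")
                 for i, x in enumerate([0.2, 0.5, 0.9])]
        intercept, _, _ = egger_intercept(pairs)
        assert intercept == pytest.approx(0.1, abs=1e-10)

    def test_orientation_flips_both_signs(self):
        base = [(0.2, 0.18), (0.5, 0.31), (0.9, 0.46), (0.4, 0.25)]
        pairs_pos = [pair(x, y, snp=f"s{i}") for i, (x, y) in enumerate(base)]
        pairs_mixed = [
            pair(-x if i % 2 else x, -y if i % 2 else y, snp=f"s{i}")
            for i, (x, y) in enumerate(base)
        ]
        assert egger_intercept(pairs_mixed) == pytest.approx(egger_intercept(pairs_pos))

    def test_matches_statsmodels_wls(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            k = int(rng.integers(3, 10))
            x = rng.uniform(0.1, 1.0, k)
            y = rng.normal(0.05 + 0.3 * x, 0.1)
            se_out = rng.uniform(0.02, 0.2, k)
            pairs = [pair(x[i], y[i], se_out=se_out[i], snp=f"s{i}") for i in range(k)]
            intercept, se, _ = egger_intercept(pairs)
            fit = sm.WLS(y, sm.add_constant(x), weights=1 / se_out**2).fit()
            assert intercept == pytest.approx(float(fit.params[0]), abs=1e-10)
            # over-dispersion floored at 1: never below the scale-1 se
            cov1 = np.linalg.inv((sm.add_constant(x).T * (1 / se_out**2)) @ sm.add_constant(x))
            assert se >= np.sqrt(cov1[0, 0]) - 1e-15

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            egger_intercept([pair(0.2, 0.1), pair(0.5, 0.2)])


class TestBH:
    def test_textbook_example(self):
        assert bh_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_single_and_ties(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert bh_adjust([0.05, 0.05]) == pytest.approx([0.05, 0.05])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    def test_matches_brute_force_step_up(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            m = int(rng.integers(1, 12))
            p = rng.uniform(0, 1, m)
            adj = bh_adjust(p)
            assert np.all(adj >= p - 1e-15) and np.all(adj <= 1 + 1e-15)
            # textbook step-up rejection set at alpha
            for alpha in (0.05, 0.2):
                order = np.argsort(p)
                k_star = 0
                for k in range(1, m + 1):
                    if p[order[k - 1]] <= k * alpha / m:
                        k_star = k
                rejected = set(order[:k_star])
                assert set(np.where(adj <= alpha + 1e-12)[0]) == rejected


class TestRunMRGene:
    def test_single_pair_routes_to_wald(self):
        res = run_mr_gene([pair(0.5, 0.2)], "G")
        assert res.method == "wald_ratio" and res.n_snps == 1
        assert res.q_statistic is None and res.egger_intercept is None
        assert res.or_value == pytest.approx(np.exp(res.beta), rel=1e-12)

    def test_five_pairs_route_to_ivw_with_egger(self):
        rng = np.random.default_rng(0)
        pairs = [pair(0.3 + 0.1 * i, rng.normal(0.1, 0.02), snp=f"s{i}")
                 for i in range(5)]
        res = run_mr_gene(pairs, "G")
        assert res.method == "ivw_random_effects"
        assert res.q_df == 4
        assert res.egger_intercept is not None

    def test_two_pairs_no_egger(self):
        res = run_mr_gene([pair(0.5, 0.2), pair(0.4, 0.15, snp="rs2")], "G")
        assert res.method == "ivw_random_effects"
        assert res.egger_intercept is None

    def test_zero_pairs_rejected(self):
        with pytest.raises(ValueError, match="not testable"):
            run_mr_gene([], "G")

    def test_ci_is_exp_of_beta_pm_196_se(self):
        res = run_mr_gene([pair(0.5, 0.2)], "G")
        assert res.ci95_low == pytest.approx(np.exp(res.beta - 1.96 * res.se), rel=1e-4)
        assert res.ci95_high == pytest.approx(np.exp(res.beta + 1.96 * res.se), rel=1e-4)
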