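"""The simulator's generative model: AR-1 LD, MVN marginal effects with
covariance r/n, scenario bookkeeping, and determinism."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from targetmr import LDMatrix, SimulationParams, SimulationTruth, make_ld_matrix, simulate_region, simulate_study
from targetmr.synthetic import largest_remainder_counts


class TestMakeLDMatrix:
    @pytest.mark.parametrize(
        "m, rho, i, j, expected",
        [(3, 0.9, 0, 2, 0.81), (5, 0.0, 1, 3, 0.0), (4, 0.5, 1, 2, 0.5)],
    )
    def test_ar1_entries(self, m, rho, i, j, expected):
        ld = make_ld_matrix(m, rho)
        assert ld.r[i, j] == pytest.approx(expected)
        assert ld.r[i, j] == ld.r[j, i]

    def test_single_snp_is_identity(self):
        assert make_ld_matrix(1, 0.7).r == pytest.approx(np.eye(1))

    def test_rho_zero_is_identity(self):
        assert make_ld_matrix(5, 0.0).r == pytest.approx(np.eye(5))

    @pytest.mark.parametrize("m, rho", [(0, 0.5), (3, 1.0), (3, -0.1)])
    def test_invalid_arguments_rejected(self, m, rho):
        with pytest.raises(ValueError):
            make_ld_matrix(m, rho)

    def test_asymmetric_matrix_rejected(self):
        r = np.array([[1.0, 0.5], [0.4, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            LDMatrix(("a", "b"), r)

    def test_non_psd_rejected_then_repairable(self):
        r = np.array([[1.0, 0.99, 0.0], [0.99, 1.0, 0.99], [0.0, 0.99, 1.0]])
        with pytest.raises(ValueError, match="PSD"):
            LDMatrix(("a", "b", "c"), r)


class TestSimulateRegion:
    def _truth(self, ld, scenario="H0", **kw):
        return SimulationTruth("G", scenario, **kw)

    def test_se_is_inverse_root_n(self):
        ld = make_ld_matrix(4, 0.3)
        truth = self._truth(ld)
        for n in (1_000, 4_000):
            exp, out = simulate_region(truth, ld, n, 16_000, seed=5)
            assert exp["se"].unique() == pytest.approx(1 / np.sqrt(n))
            assert out["se"].unique() == pytest.approx(1 / np.sqrt(16_000))
        # se scales as 1/sqrt(n): quadrupling n halves it
        e1, _ = simulate_region(truth, ld, 1_000, 1_000, seed=5)
        e4, _ = simulate_region(truth, ld, 4_000, 1_000, seed=5)
        assert e4["se"].iloc[0] == pytest.approx(e1["se"].iloc[0] / 2)
        e2, _ = simulate_region(truth, ld, 2_000, 1_000, seed=5)
        assert e2["se"].iloc[0] == pytest.approx(e1["se"].iloc[0] / np.sqrt(2))

    def test_null_z2_mean_near_one(self):
        ld = make_ld_matrix(1_000, 0.0)
        exp, out = simulate_region(self._truth(ld), ld, 50_000, 50_000, seed=9)
        for df in (exp, out):
            z2 = (df["beta"] / df["se"]) ** 2
            assert 0.85 <= z2.mean() <= 1.15

    def test_h4_outcome_beta_at_causal(self):
        ld = make_ld_matrix(3, 0.0)
        snp = ld.snp_ids[1]
        truth = SimulationTruth(
            "G", "H4", causal_exposure_snp=snp, causal_outcome_snp=snp,
            beta_exposure_causal=0.5, theta=0.4,
        )
        _, out = simulate_region(truth, ld, 100_000, 100_000, seed=3)
        row = out[out["snp_id"] == snp].iloc[0]
        assert abs(row["beta"] - 0.2) < 5 * row["se"]

    def test_determinism(self):
        ld = make_ld_matrix(6, 0.5)
        truth = self._truth(ld, "H1", causal_exposure_snp=ld.snp_ids[0],
                            beta_exposure_causal=0.3)
        a = simulate_region(truth, ld, 5_000, 8_000, seed=11)
        b = simulate_region(truth, ld, 5_000, 8_000, seed=11)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
        c = simulate_region(truth, ld, 5_000, 8_000, seed=12)
        assert not a[0]["beta"].equals(c[0]["beta"])

    def test_pvalues_match_normal_tails(self):
        from targetmr.records import validate_summary_frame

        ld = make_ld_matrix(10, 0.4)
        exp, out = simulate_region(self._truth(ld), ld, 2_000, 2_000, seed=2)
        validate_summary_frame(exp, check_pvalues=True)
        validate_summary_frame(out, check_pvalues=True)

    def test_unknown_causal_snp_rejected(self):
        ld = make_ld_matrix(3, 0.0)
        truth = SimulationTruth("G", "H1", causal_exposure_snp="rs_nope",
                                beta_exposure_causal=0.3)
        with pytest.raises(ValueError, match="not in the LD matrix"):
            simulate_region(truth, ld, 1_000, 1_000, seed=0)

    def test_z_correlation_reproduces_ld(self):
        m, reps = 4, 2_000
        ld = make_ld_matrix(m, 0.6)
        zs = np.empty((reps, m))
        truth = self._truth(ld)
        for rep in range(reps):
            exp, _ = simulate_region(truth, ld, 10_000, 1_000, seed=rep)
            zs[rep] = exp["beta"] / exp["se"]
        emp = np.corrcoef(zs.T)
        assert np.max(np.abs(emp - ld.r)) < 0.05

    def test_uncorrelated_snp_has_zero_mean_beta(self):
        ld = make_ld_matrix(2, 0.0)
        truth = SimulationTruth("G", "H1", causal_exposure_snp=ld.snp_ids[0],
                                beta_exposure_causal=0.5)
        betas = [
            simulate_region(truth, ld, 10_000, 1_000, seed=rep)[0]["beta"].iloc[1]
            for rep in range(400)
        ]
        se_mean = 1 / np.sqrt(10_000) / np.sqrt(400)
        assert abs(np.mean(betas)) < 4 * se_mean


class TestSimulationTruth:
    @pytest.mark.parametrize(
        "scenario, kw",
        [
            ("H0", {"causal_exposure_snp": "rs1"}),
            ("H1", {}),
            ("H2", {"causal_exposure_snp": "rs1", "causal_outcome_snp": "rs1"}),
            ("H3", {"causal_exposure_snp": "rs1", "causal_outcome_snp": "rs1"}),
            ("H4", {"causal_exposure_snp": "rs1", "causal_outcome_snp": "rs2"}),
            ("H1", {"causal_exposure_snp": "rs1", "theta": 0.4}),
        ],
    )
    def test_inconsistent_truths_rejected(self, scenario, kw):
        with pytest.raises(ValueError):
            SimulationTruth("G", scenario, **kw)


class TestSimulateStudy:
    def test_scenario_counts_follow_largest_remainder(self):
        mix = (0.5, 0.1, 0.1, 0.1, 0.2)
        bundle = simulate_study(50, mix, SimulationParams(m_snps=5), seed=1)
        counts = pd.Series(bundle.scenarios).value_counts()
        assert counts["H0"] == 25 and counts["H4"] == 10
        assert len(bundle.scenarios) == 50
        assert len(bundle.truths) == 2 * 50  # one record per gene per tissue

    def test_all_h0_mix_has_no_causal_snps(self):
        bundle = simulate_study(8, (1, 0, 0, 0, 0), SimulationParams(m_snps=4), seed=2)
        for truth in bundle.truths.values():
            assert truth.causal_exposure_snp is None
            assert truth.causal_outcome_snp is None

    def test_bundle_determinism(self):
        p = SimulationParams(m_snps=6)
        a = simulate_study(6, (0.5, 0.1, 0.1, 0.1, 0.2), p, seed=3)
        b = simulate_study(6, (0.5, 0.1, 0.1, 0.1, 0.2), p, seed=3)
        for t in a.exposures:
            pd.testing.assert_frame_equal(a.exposures[t], b.exposures[t])
            pd.testing.assert_frame_equal(a.outcomes[t], b.outcomes[t])
        assert a.scenarios == b.scenarios
        assert a.gene_sets == b.gene_sets

    def test_druggable_lists_overlap_and_cover_genes(self, small_bundle):
        a = set(small_bundle.druggable["source_a"])
        b = set(small_bundle.druggable["source_b"])
        genes = set(small_bundle.genes["symbol"])
        assert a & b  # partial overlap exercises the merge
        assert a - b and b - a
        assert genes <= (a | b)

    def test_at_least_one_h4_when_mix_positive(self):
        # tiny H4 mass that floors to zero still yields one H4 gene
        bundle = simulate_study(10, (0.9, 0.04, 0.02, 0.02, 0.02),
                                SimulationParams(m_snps=4), seed=4)
        assert "H4" in bundle.scenarios.values()

    @pytest.mark.parametrize("bad", [0, -3])
    def test_bad_n_genes_rejected(self, bad):
        with pytest.raises(ValueError):
            simulate_study(bad, (1, 0, 0, 0, 0), seed=0)

    def test_bad_mix_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            simulate_study(5, (0.5, 0.1, 0.1, 0.1, 0.1), seed=0)


class TestLargestRemainder:
    def test_example(self):
        assert largest_remainder_counts(50, (0.5, 0.1, 0.1, 0.1, 0.2)) == [25, 5, 5, 5, 10]

    @settings(max_examples=50, derandomize=True)
    @given(
        n=st.integers(1, 200),
        weights=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
    )
    def test_counts_sum_and_stay_close(self, n, weights):
        p = np.array(weights) / np.sum(weights)
        counts = largest_remainder_counts(n, p)
        assert sum(counts) == n
        assert all(abs(c - n * pi) < 1 for c, pi in zip(counts, p))
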