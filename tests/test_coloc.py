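"""Colocalization: per-SNP approximate Bayes factors and the
five-hypothesis posterior enumeration."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from targetmr import ColocPriors, coloc_abf, coloc_window_extract, log_abf
from targetmr.calibration import enumerate_coloc_log_posteriors


def frames(z1, z2, se1=0.1, se2=0.01):
    m = len(z1)
    ids = [f"s{i}" for i in range(m)]
    se1 = np.broadcast_to(np.asarray(se1, float), (m,))
    se2 = np.broadcast_to(np.asarray(se2, float), (m,))
    eqtl = pd.DataFrame({"snp_id": ids, "beta": np.asarray(z1) * se1, "se": se1})
    gwas = pd.DataFrame({"snp_id": ids, "beta": np.asarray(z2) * se2, "se": se2})
    return eqtl, gwas


class TestLogABF:
    def test_direct_evaluation(self):
        # r = 0.04/(0.01+0.04) = 0.8, z = 2
        assert log_abf(0.2, 0.1, 0.04) == pytest.approx(0.5 * (np.log(0.2) + 3.2))
        assert log_abf(0.2, 0.1, 0.04) == pytest.approx(0.79528, abs=1e-5)

    def test_null_z_favors_null(self):
        assert log_abf(0.0, 0.1, 0.04) == pytest.approx(0.5 * np.log(0.2))
        assert log_abf(0.0, 0.1, 0.04) == pytest.approx(-0.80472, abs=1e-5)

    def test_degenerate_prior_limit(self):
        for z in (0.0, 3.0, -8.0):
            assert log_abf(z * 0.1, 0.1, 1e-14) == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("se, w", [(0.0, 0.04), (-0.1, 0.04), (0.1, 0.0)])
    def test_invalid_inputs_rejected(self, se, w):
        with pytest.raises(ValueError):
            log_abf(0.2, se, w)


class TestPriors:
    def test_defaults(self):
        p = ColocPriors()
        assert (p.p1, p.p2, p.p12) == (1e-4, 1e-4, 1e-5)

    def test_p12_bounded_by_marginals(self):
        with pytest.raises(ValueError):
            ColocPriors(p1=1e-5, p2=1e-4, p12=1e-4)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ColocPriors(p1=0.0)


class TestColocABF:
    def test_single_null_snp_hand_normalization(self):
        # lABF1 = lABF2 = 0 via a degenerate prior variance
        eqtl, gwas = frames([0.0], [0.0])
        priors = ColocPriors(w_quant=1e-16, w_cc=1e-16)
        res = coloc_abf(eqtl, gwas, priors)
        weights = np.array([1.0, 1e-4, 1e-4, 0.0, 1e-5])
        expected = weights / weights.sum()
        assert res.pph0 == pytest.approx(expected[0], abs=1e-6)
        assert res.pph0 == pytest.approx(0.99979, abs=1e-4)
        assert res.pph3 == 0.0  # exactly: S1*S2 == S12 for m = 1
        assert res.pph4 == pytest.approx(expected[4], rel=1e-4)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(21)
        priors = ColocPriors()
        for _ in range(40):
            m = int(rng.integers(2, 13))
            eqtl, gwas = frames(rng.normal(0, 3, m), rng.normal(0, 3, m),
                                se1=rng.uniform(0.05, 0.2, m),
                                se2=rng.uniform(0.005, 0.02, m))
            res = coloc_abf(eqtl, gwas, priors)
            ref = enumerate_coloc_log_posteriors(
                eqtl["beta"].to_numpy(), eqtl["se"].to_numpy(),
                gwas["beta"].to_numpy(), gwas["se"].to_numpy(), priors)
            assert np.log(res.posteriors) == pytest.approx(ref, abs=1e-8)

    def test_posteriors_sum_to_one_and_reorder_invariant(self):
        rng = np.random.default_rng(8)
        eqtl, gwas = frames(rng.normal(0, 4, 20), rng.normal(0, 4, 20))
        res = coloc_abf(eqtl, gwas)
        assert res.posteriors.sum() == pytest.approx(1.0, abs=1e-12)
        shuffled = coloc_abf(eqtl.sample(frac=1, random_state=1), gwas)
        assert shuffled.posteriors == pytest.approx(res.posteriors, abs=1e-12)

    def test_h4_h1_ratio_identity(self):
        # exact algebra: H4/H1 = (p12/p1) * (S12/S1)
        rng = np.random.default_rng(13)
        priors = ColocPriors()
        eqtl, gwas = frames(rng.normal(2, 2, 15), rng.normal(2, 2, 15))
        res = coloc_abf(eqtl, gwas, priors)
        l1 = log_abf(eqtl["beta"].to_numpy(), eqtl["se"].to_numpy(), priors.w_quant)
        l2 = log_abf(gwas["beta"].to_numpy(), gwas["se"].to_numpy(), priors.w_cc)
        log_ratio = (np.log(priors.p12 / priors.p1)
                     + logsumexp(l1 + l2) - logsumexp(l1))
        assert np.log(res.pph4 / res.pph1) == pytest.approx(log_ratio, abs=1e-10)

    def test_strong_shared_signal_passes_threshold(self):
        z = np.zeros(30)
        z[7] = 9.0
        eqtl, gwas = frames(z, z * 1.1)
        res = coloc_abf(eqtl, gwas)
        assert res.pph4 >= 0.75 and res.passes_threshold

    def test_empty_intersection_not_colocalizable(self):
        eqtl, _ = frames([1.0, 2.0], [0.0, 0.0])
        gwas = pd.DataFrame({"snp_id": ["x1"], "beta": [0.1], "se": [0.01]})
        with pytest.raises(ValueError, match="not colocalizable"):
            coloc_abf(eqtl, gwas, gene="G1")

    def test_large_region_prior_warning(self, caplog):
        eqtl, gwas = frames(np.zeros(5), np.zeros(5))
        with caplog.at_level("WARNING"):
            coloc_abf(eqtl, gwas, ColocPriors(p1=0.1, p2=0.1, p12=0.05))
        assert "priors" in caplog.text


class TestWindowExtract:
    def _tables(self):
        gwas = pd.DataFrame({"snp_id": ["a", "b", "c"], "chrom": "1",
                             "pos": [900_000, 1_100_000, 1_100_001],
                             "beta": 0.1, "se": 0.01})
        eqtl = pd.DataFrame({"snp_id": ["a", "c", "d"], "chrom": "1",
                             "pos": [900_000, 1_100_001, 1_000_000],
                             "beta": 0.2, "se": 0.02})
        return gwas, eqtl

    def test_closed_boundary_and_inner_join(self):
        gwas, eqtl = self._tables()
        eqtl_r, gwas_r = coloc_window_extract(gwas, eqtl, 1_000_000, 100_000)
        # 'a' at tss-100000 is inside (closed window) and shared;
        # 'b' only in GWAS; 'c' is 1 bp outside; 'd' only in eQTL
        assert list(eqtl_r["snp_id"]) == ["a"]
        assert list(gwas_r["snp_id"]) == ["a"]

    def test_empty_join(self):
        gwas, eqtl = self._tables()
        eqtl_r, gwas_r = coloc_window_extract(gwas, eqtl.iloc[2:], 1_000_000, 10)
        assert len(eqtl_r) == 0 and len(gwas_r) == 0
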