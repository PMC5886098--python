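"""Cross-phenotype statistics, IVW meta-analysis and the sign test."""

import numpy as np
import pytest
from scipy import stats

from crosstrait import (StudyCorrMatrix, estimate_corr_matrix, ivw_meta,
                        s_het, s_het_batch, s_hom, sign_test,
                        SimConfig, build_panel, simulate_polygenic_pair)


def R_eye(k=2):
    return StudyCorrMatrix([f"s{i}" for i in range(k)], np.eye(k))


class TestShom:
    def test_equal_weights_equal_z(self):
        stat, p = s_hom([2.0, 2.0], [10_000.0, 10_000.0], R_eye())
        assert stat == pytest.approx(8.0)
        assert p == pytest.approx(stats.chi2.sf(8.0, 1))
        assert p == pytest.approx(4.68e-3, rel=1e-2)

    def test_opposite_z_cancel(self):
        stat, _ = s_hom([2.0, -2.0], [10_000.0, 10_000.0], R_eye())
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_single_study_reduces_to_z_squared(self):
        stat, p = s_hom([1.7], [5000.0], R_eye(1))
        assert stat == pytest.approx(1.7 ** 2)
        assert p == pytest.approx(2 * stats.norm.sf(1.7), rel=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_sign_flip_invariance(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.normal(size=3, scale=2)
        n = rng.uniform(1e3, 1e5, size=3)
        R = StudyCorrMatrix(["a", "b", "c"],
                            0.4 * np.ones((3, 3)) + 0.6 * np.eye(3))
        assert s_hom(z, n, R)[0] == pytest.approx(s_hom(-z, n, R)[0], rel=1e-12)

    def test_ivw_equivalence_anchor(self):
        """With R = I and inverse-variance weights, S_hom equals the
        squared IVW meta Z — the defining equivalence."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            k = rng.integers(2, 5)
            betas = rng.normal(size=k)
            ses = rng.uniform(0.02, 0.5, size=k)
            z = betas / ses
            # weights 1/se equal sqrt(n) when n = 1/se^2
            stat, _ = s_hom(z, 1.0 / ses ** 2, R_eye(k))
            mr = ivw_meta(betas, ses)
            z_meta = mr.pooled_beta / mr.pooled_se
            assert stat == pytest.approx(z_meta ** 2, rel=1e-10)


class TestShet:
    def test_floor_is_all_studies_statistic(self):
        z = [0.3, -0.2]
        n = [1e4, 1e4]
        stat, p, tau = s_het(z, n, R_eye(), n_mc=200, seed=1)
        assert stat == pytest.approx(s_hom(z, n, R_eye())[0], rel=1e-12)
        assert tau == 0.0

    def test_heterogeneous_signal_beats_shom(self):
        z = [6.0, 0.3]
        n = [1e4, 1e4]
        stat, _, tau = s_het(z, n, R_eye(), n_mc=200, seed=2)
        assert stat >= s_hom(z, n, R_eye())[0]
        assert stat == pytest.approx(36.0)  # tau isolating study 1
        assert tau > 0

    def test_sign_flip_invariance(self):
        z = np.array([1.2, -2.5])
        n = np.array([1e4, 2e4])
        R = StudyCorrMatrix(["a", "b"], np.array([[1, 0.3], [0.3, 1]]))
        s1, _, _ = s_het(z, n, R, n_mc=200, seed=3)
        s2, _, _ = s_het(-z, n, R, n_mc=200, seed=3)
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            s_het([1.0, 1.0], [1e4, 1e4], R_eye(), tau_grid=(0.5, 1.0))
        with pytest.raises(ValueError):
            s_het([1.0, 1.0], [1e4, 1e4], R_eye(), n_mc=50)

    def test_null_calibration(self):
        R = StudyCorrMatrix(["a", "b"], np.array([[1, 0.3], [0.3, 1]]))
        rng = np.random.default_rng(11)
        L = np.linalg.cholesky(R.R)
        Z = rng.standard_normal((1000, 2)) @ L.T
        _, p, _ = s_het_batch(Z, np.array([1e4, 1e4]), R, n_mc=5000, seed=4)
        rej = (p <= 0.05).mean()
        assert abs(rej - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 1000)


class TestCorrMatrix:
    def test_psd_validation(self):
        with pytest.raises(ValueError):
            StudyCorrMatrix(["a", "b"], np.array([[1.0, 1.5], [1.5, 1.0]]))

    def test_duplicate_study_repaired(self):
        cfg = SimConfig(m_snps=3000, seed=5, h2_1=0.0, h2_2=0.0, rg=0.0,
                        overlap_c=0.0)
        blocks, mats = build_panel(cfg)
        a, b, _ = simulate_polygenic_pair(cfg, (blocks, mats))
        R = estimate_corr_matrix([a, a], blocks, mats)
        assert R.repaired
        assert np.linalg.eigvalsh(R.R).min() > 0

    def test_independent_null_off_diagonal_small(self):
        cfg = SimConfig(m_snps=50_000, seed=6, h2_1=0.0, h2_2=0.0, rg=0.0,
                        overlap_c=0.0)
        blocks, mats = build_panel(cfg)
        a, b, _ = simulate_polygenic_pair(cfg, (blocks, mats))
        R = estimate_corr_matrix([a, b], blocks, mats)
        assert abs(R.R[0, 1]) < 0.02


class TestIvwMeta:
    def test_equal_studies_average(self):
        mr = ivw_meta([0.1, 0.1], [0.1, 0.1])
        assert mr.pooled_beta == pytest.approx(0.1)
        assert mr.pooled_se == pytest.approx(0.1 / np.sqrt(2))
        assert mr.or_ == pytest.approx(np.exp(0.1))
        assert mr.ci95[0] == pytest.approx(np.exp(0.1 - 1.96 * mr.pooled_se))

    def test_equal_precision_midpoint(self):
        assert ivw_meta([0.2, 0.0], [0.1, 0.1]).pooled_beta == pytest.approx(0.1)

    def test_single_study_passthrough(self):
        mr = ivw_meta([0.25], [0.07])
        assert mr.pooled_beta == pytest.approx(0.25)
        assert mr.pooled_se == pytest.approx(0.07)

    def test_missing_study_marked(self):
        mr = ivw_meta([0.1, np.nan, -0.2], [0.1, np.nan, 0.1])
        assert mr.direction_string == "+?-"
        assert mr.n_studies == 2

    def test_pooled_se_never_exceeds_smallest(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            ses = rng.uniform(0.01, 1.0, size=rng.integers(1, 6))
            mr = ivw_meta(rng.normal(size=len(ses)), ses)
            assert mr.pooled_se <= ses.min() + 1e-12

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            ivw_meta([np.nan], [np.nan])


class TestSignTest:
    def test_full_concordance_doubled_tail(self):
        # 10/10 concordant across 3 studies: p = 2 * 0.25^10
        p = sign_test(["+++"] * 10, 3)
        assert p == pytest.approx(2 * 0.25 ** 10, rel=1e-9)
        assert p == pytest.approx(1.91e-6, rel=1e-2)

    def test_null_expectation_not_significant(self):
        strings = ["++"] * 5 + ["+-"] * 5
        assert sign_test(strings, 2) >= 0.5

    def test_missing_direction_excluded(self):
        p_with = sign_test(["+++"] * 5 + ["+?+"], 3)
        p_without = sign_test(["+++"] * 5, 3)
        assert p_with == pytest.approx(p_without)

    def test_no_eligible_raises(self):
        with pytest.raises(ValueError):
            sign_test(["+?"], 2)


def test_p_hom_null_uniformity():
    """p_hom is uniform under a correlated null (KS check)."""
    R = StudyCorrMatrix(["a", "b"], np.array([[1, 0.3], [0.3, 1]]))
    rng = np.random.default_rng(21)
    L = np.linalg.cholesky(R.R)
    Z = rng.standard_normal((5000, 2)) @ L.T
    w = np.sqrt(np.array([1e4, 1e4]))
    Rinv_w = np.linalg.solve(R.R, w)
    shom = (Z @ Rinv_w) ** 2 / (w @ Rinv_w)
    p = stats.chi2.sf(shom, 1)
    assert stats.kstest(p, "uniform").statistic < 0.025
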