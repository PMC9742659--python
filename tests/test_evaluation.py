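"""Voxel-wise metrics, SSIM, joint-histogram R^2, and the comparison stats."""

import numpy as np
import pytest
from scipy import stats

from fedpet.evaluation import (
    EvalMask,
    MetricsReport,
    compare_strategies,
    joint_histogram_r2,
    reports_to_frame,
    ssim,
    voxel_metrics,
)

FULL = EvalMask(rule="whole")


def naive_gaussian_ssim(a, b, data_range=5.0, sigma=1.5, win=11):
    """Independent SSIM: explicit Gaussian-window moments at every pixel."""
    from scipy.ndimage import gaussian_filter

    a = a.astype(float)
    b = b.astype(float)
    trunc = (win - 1) / 2 / sigma  # 11-px window
    f = lambda x: gaussian_filter(x, sigma, truncate=trunc, mode="reflect")
    mu_a, mu_b = f(a), f(b)
    va = f(a * a) - mu_a**2
    vb = f(b * b) - mu_b**2
    cab = f(a * b) - mu_a * mu_b
    C1 = (0.01 * data_range) ** 2
    C2 = (0.03 * data_range) ** 2
    s = ((2 * mu_a * mu_b + C1) * (2 * cab + C2)) / (
        (mu_a**2 + mu_b**2 + C1) * (va + vb + C2)
    )
    pad = (win - 1) // 2
    return float(s[pad:-pad, pad:-pad].mean())


class TestVoxelMetrics:
    def test_hand_evaluated_fixture(self):
        """pred=[1,2,3] vs ref=[2,2,2]: ME=0, MAE=2/3, RE=0, ARE=33.33%,
        MSE=2/3, Peak=2, PSNR=10 log10(6)."""
        r = voxel_metrics(np.array([[1.0, 2.0, 3.0]]), np.array([[2.0, 2.0, 2.0]]), FULL)
        assert r.ME == pytest.approx(0.0, abs=1e-9)
        assert r.MAE == pytest.approx(2.0 / 3.0, abs=1e-9)
        assert r.RE_pct == pytest.approx(0.0, abs=1e-9)
        assert r.ARE_pct == pytest.approx(100.0 / 3.0, abs=1e-6)
        assert r.peak == 2.0
        assert r.PSNR_dB == pytest.approx(10 * np.log10(6.0), abs=1e-9)
        assert r.vxl == 3

    def test_identity_gives_zero_errors_and_infinite_psnr(self, rng):
        img = rng.random((32, 32)) + 0.1
        r = voxel_metrics(img, img, FULL)
        assert r.ME == r.MAE == r.RE_pct == r.ARE_pct == 0.0
        assert np.isinf(r.PSNR_dB)
        assert r.SSIM == pytest.approx(1.0)

    def test_swapping_pred_and_ref_negates_signed_metrics(self):
        pred = np.array([[1.0, 2.0, 3.0]])
        ref = np.array([[2.0, 2.0, 2.0]])
        fwd = voxel_metrics(pred, ref, FULL)
        rev = voxel_metrics(ref, pred, FULL)
        assert rev.ME == -fwd.ME
        assert rev.MAE == fwd.MAE
        # ARE is not symmetric: the denominator changes
        assert rev.ARE_pct == pytest.approx(100.0 * (1.0 + 0 + 1.0 / 3.0) / 3.0)
        assert rev.ARE_pct != pytest.approx(fwd.ARE_pct)

    def test_mask_restricts_voxel_count(self, rng):
        ref = rng.random((16, 16))
        pred = ref + 0.01
        r = voxel_metrics(pred, ref, EvalMask(tau=0.5))
        assert r.vxl == int((ref > 0.5).sum())

    def test_mae_bounds_me_and_are_bounds_re(self, rng):
        """Jensen-type inequalities on random pairs."""
        for _ in range(20):
            ref = rng.random((12, 12)) + 0.2
            pred = ref + rng.standard_normal((12, 12)) * 0.3
            r = voxel_metrics(pred, ref, FULL)
            assert r.MAE >= abs(r.ME)
            assert r.ARE_pct >= abs(r.RE_pct)

    def test_psnr_decreases_with_noise_level(self, rng):
        ref = rng.random((32, 32)) + 0.5
        noise = rng.standard_normal((32, 32))
        psnrs = [
            voxel_metrics(ref + s * noise, ref, FULL).PSNR_dB
            for s in (0.01, 0.05, 0.2)
        ]
        assert psnrs[0] > psnrs[1] > psnrs[2]

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError, match="mask"):
            voxel_metrics(np.ones((4, 4)), np.full((4, 4), 1e-6), EvalMask(tau=0.5))


class TestSSIM:
    def test_identity_is_one(self, rng):
        img = rng.random((32, 32)) * 5
        assert ssim(img, img) == pytest.approx(1.0)

    def test_anticorrelated_images_score_negative(self):
        """A sign flip drives SSIM negative when local window means vanish
        (then only the anti-correlated covariance term carries sign); a
        short-period zero-mean pattern realizes that regime."""
        y = np.arange(32)
        img = np.sin(2 * np.pi * y / 4)[:, None] * np.ones((1, 32))
        assert ssim(-img, img) < 0

    def test_matches_independent_implementation(self, rng):
        """Agreement with a hand-rolled Gaussian-window SSIM on random pairs."""
        for _ in range(10):
            a = rng.random((48, 48)) * 5
            b = np.clip(a + rng.standard_normal((48, 48)) * rng.uniform(0.1, 1.0), 0, 5)
            assert ssim(a, b) == pytest.approx(naive_gaussian_ssim(a, b), abs=0.02)

    def test_uniform_offset_pulls_luminance_below_one(self, rng):
        a = rng.random((32, 32))
        val = ssim(a + 2.0, a)
        assert 0 < val < 1


class TestJointHistogramR2:
    def test_identity_gives_unit_r2_and_diagonal_mass(self, rng):
        ref = [rng.random((16, 16)) * 4 + 0.5 for _ in range(3)]
        hist, r2, slope = joint_histogram_r2(ref, ref, EvalMask(tau=0.0), bins=64)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)
        # all mass within one bin of the diagonal
        i, j = np.nonzero(hist)
        assert np.all(np.abs(i - j) <= 1)

    def test_exact_scaling_keeps_r2_at_one_with_slope(self, rng):
        ref = [rng.random((16, 16)) * 4 + 0.5]
        pred = [0.9 * r for r in ref]
        _, r2, slope = joint_histogram_r2(pred, ref, EvalMask(tau=0.0))
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(0.9)

    def test_noise_attenuates_r2_as_variance_ratio(self, rng):
        """R^2 -> Var(ref) / (Var(ref) + sigma^2) for independent noise."""
        ref = rng.random((200, 200)) * 4 + 0.5
        sigma = 0.5
        pred = ref + sigma * rng.standard_normal(ref.shape)
        _, r2, _ = joint_histogram_r2([pred], [ref], EvalMask(tau=0.0))
        expected = ref.var() / (ref.var() + sigma**2)
        assert r2 == pytest.approx(expected, rel=0.03)

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            joint_histogram_r2([np.ones((8, 8))], [np.ones((8, 8))],
                               EvalMask(rule="whole"))


def make_reports(strategy, values, metric="ARE_pct"):
    reports = []
    for i, v in enumerate(values):
        kw = dict(ME=0.0, MAE=0.1, RE_pct=0.0, ARE_pct=10.0, PSNR_dB=30.0, SSIM=0.9)
        kw[metric] = v
        reports.append(MetricsReport(study_id=f"s{i}", strategy=strategy,
                                     vxl=100, peak=5.0, **kw))
    return reports


class TestCompareStrategies:
    def test_identical_samples_not_significant(self):
        reports = make_reports("A", [1.0, 2.0, 3.0]) + make_reports("B", [1.0, 2.0, 3.0])
        results = compare_strategies(reports, metrics=("ARE_pct",))
        assert results[0].p_value == pytest.approx(1.0)
        assert not results[0].significant

    def test_exact_mann_whitney_p_for_separated_samples(self):
        """{1,2,3} vs {10,11,12}: U=0, exact two-sided p = 2/20 = 0.1."""
        reports = make_reports("A", [1.0, 2.0, 3.0]) + make_reports("B", [10.0, 11.0, 12.0])
        results = compare_strategies(reports, metrics=("ARE_pct",))
        assert results[0].p_value == pytest.approx(0.1)

    def test_mann_whitney_matches_exact_enumeration(self, rng):
        """Two-sided p agrees with brute-force enumeration of all C(n+m, n)
        group assignments on random tie-free samples."""
        from itertools import combinations

        for _ in range(20):
            n, m = int(rng.integers(3, 6)), int(rng.integers(3, 6))
            pooled = rng.permutation(rng.random(n + m))  # ties a.s. absent
            x, y = pooled[:n], pooled[n:]
            u_obs = sum((xi > yj) for xi in x for yj in y)
            u_min = min(u_obs, n * m - u_obs)
            count = 0
            total = 0
            idx = range(n + m)
            for comb in combinations(idx, n):
                sel = np.zeros(n + m, bool)
                sel[list(comb)] = True
                u = sum((xi > yj) for xi in pooled[sel] for yj in pooled[~sel])
                total += 1
                if min(u, n * m - u) <= u_min:
                    count += 1
            p_exact = count / total
            p_scipy = stats.mannwhitneyu(x, y, alternative="two-sided",
                                         method="exact").pvalue
            assert p_scipy == pytest.approx(p_exact, abs=1e-12)

    def test_bh_step_up_hand_fixture(self):
        """BH on (0.01, 0.02, 0.04, 0.05) gives q = (0.04, 0.04, 0.05, 0.05)."""
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests([0.01, 0.02, 0.04, 0.05], method="fdr_bh")
        np.testing.assert_allclose(q, [0.04, 0.04, 0.05, 0.05])

    def test_q_values_dominate_p_values_and_flag_significance(self, rng):
        reports = []
        for s in ("A", "B", "C"):
            shift = {"A": 0.0, "B": 0.2, "C": 5.0}[s]
            reports += make_reports(s, list(10 + shift + rng.random(8)))
        results = compare_strategies(reports, metrics=("ARE_pct", "MAE"))
        for r in results:
            assert r.q_value >= r.p_value - 1e-15
            assert r.significant == (r.q_value < 0.05)

    def test_invariant_to_study_ordering(self, rng):
        a = make_reports("A", list(rng.random(6)))
        b = make_reports("B", list(rng.random(6) + 0.5))
        fwd = compare_strategies(a + b, metrics=("ARE_pct",))
        rev = compare_strategies(list(reversed(a + b)), metrics=("ARE_pct",))
        assert fwd[0].p_value == rev[0].p_value
        assert fwd[0].q_value == rev[0].q_value

    def test_too_few_studies_rejected(self):
        reports = make_reports("A", [1.0, 2.0]) + make_reports("B", [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match=">= 3"):
            compare_strategies(reports, metrics=("ARE_pct",))
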