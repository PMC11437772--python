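import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_stack
from oracles import oracle_decorrelation, oracle_inertia_moment, oracle_tlasca
from specklestress.metrics import (
    AnalysisConfig,
    DecorrelationCurve,
    NoMeasurableDecayError,
    analyze_stack,
    compute_decorrelation_curve,
    compute_inertia_moment,
    compute_tlasca,
)


# ---------------------------------------------------------------- decorrelation


class TestDecorrelationCurve:
    def test_static_stack_all_ones(self, static_stack):
        curve = compute_decorrelation_curve(static_stack, 9)
        np.testing.assert_allclose(curve.corr, 1.0, atol=1e-12)

    def test_iid_noise_near_zero(self, rng):
        frames = rng.integers(0, 256, size=(40, 32, 32), dtype=np.uint8)
        stack = make_stack(frames)
        curve = compute_decorrelation_curve(stack, 10)
        assert curve.corr[0] == 1.0
        # independence: |corr| ~ 1/sqrt(n_pixels), allow 4x margin
        assert np.all(np.abs(curve.corr[1:]) < 4 / np.sqrt(32 * 32))

    def test_three_frame_hand_example(self):
        # f0=(1,2,3,4), f1=(2,3,4,5), f2=(4,3,2,1):
        # lag 1 = mean(rho(f0,f1), rho(f1,f2)) = mean(1, -1) = 0
        # lag 2 = rho(f0,f2) = -1
        frames = np.array(
            [[[1, 2], [3, 4]], [[2, 3], [4, 5]], [[4, 3], [2, 1]]], dtype=np.uint8
        )
        curve = compute_decorrelation_curve(make_stack(frames), 2)
        np.testing.assert_allclose(curve.corr, [1.0, 0.0, -1.0], atol=1e-12)
        np.testing.assert_array_equal(curve.n_pairs, [3, 2, 1])
        np.testing.assert_allclose(curve.lags, [0, 1 / 30, 2 / 30])

    def test_degenerate_frame_names_index(self, rng):
        frames = rng.integers(0, 256, size=(5, 4, 4), dtype=np.uint8)
        frames[3] = 7  # constant frame -> zero pixel variance
        with pytest.raises(ValueError, match="frame 3"):
            compute_decorrelation_curve(make_stack(frames), 4)

    def test_max_lag_bounds(self, random_stack):
        with pytest.raises(ValueError, match="max_lag_frames"):
            compute_decorrelation_curve(random_stack, random_stack.n_frames)
        with pytest.raises(ValueError, match="max_lag_frames"):
            compute_decorrelation_curve(random_stack, 0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            t = int(rng.integers(4, 21))
            h = int(rng.integers(3, 17))
            w = int(rng.integers(3, 17))
            frames = rng.integers(0, 256, size=(t, h, w), dtype=np.uint8)
            stack = make_stack(frames)
            max_lag = t - 1
            curve = compute_decorrelation_curve(stack, max_lag)
            expected = oracle_decorrelation(frames, max_lag)
            np.testing.assert_allclose(curve.corr, expected, atol=1e-12)

    def test_first_frame_mode(self, rng):
        frames = rng.integers(0, 256, size=(6, 8, 8), dtype=np.uint8)
        stack = make_stack(frames)
        curve = compute_decorrelation_curve(stack, 5, mode="first_frame")
        from oracles import pearson

        for k in range(1, 6):
            assert curve.corr[k] == pytest.approx(pearson(frames[0], frames[k]), abs=1e-12)
        assert np.all(curve.n_pairs == 1)

    def test_scale_invariance(self, rng):
        frames = rng.integers(0, 80, size=(8, 8, 8), dtype=np.uint8)
        a = compute_decorrelation_curve(make_stack(frames), 5)
        b = compute_decorrelation_curve(make_stack(frames * 3), 5)
        np.testing.assert_allclose(a.corr, b.corr, atol=1e-12)

    def test_curve_validation(self):
        with pytest.raises(ValueError, match="lag 0"):
            DecorrelationCurve(
                lags=np.array([0.0, 0.1, 0.2]),
                corr=np.array([0.9, 0.5, 0.2]),
                n_pairs=np.array([3, 2, 1]),
            )
        with pytest.raises(ValueError, match="at least 3"):
            DecorrelationCurve(
                lags=np.array([0.0, 0.1]),
                corr=np.array([1.0, 0.5]),
                n_pairs=np.array([2, 1]),
            )


# --------------------------------------------------------------------- tlasca


class TestTlasca:
    def test_constant_video_is_zero(self, static_stack):
        assert compute_tlasca(static_stack) == 0.0

    def test_single_pixel_hand_example(self):
        # intensities (2, 4): sample std sqrt(2), mean 3 -> sqrt(2)/3
        stack = make_stack(np.array([[[2]], [[4]]]))
        assert compute_tlasca(stack) == pytest.approx(np.sqrt(2) / 3, abs=1e-12)

    def test_two_pixel_spatial_average(self):
        # pixel A constant 5 (ratio 0), pixel B (2,4) -> mean(0, sqrt(2)/3)
        frames = np.array([[[5, 2]], [[5, 4]]])
        stack = make_stack(frames)
        assert compute_tlasca(stack) == pytest.approx(np.sqrt(2) / 6, abs=1e-12)

    def test_matches_loop_oracle(self, rng):
        for _ in range(20):
            frames = rng.integers(0, 256, size=(10, 8, 8), dtype=np.uint8)
            stack = make_stack(frames)
            assert compute_tlasca(stack) == pytest.approx(oracle_tlasca(frames), abs=1e-12)

    def test_zero_mean_pixel_excluded_by_default(self, rng):
        frames = rng.integers(1, 256, size=(5, 4, 4), dtype=np.uint8)
        frames[:, 0, 0] = 0
        stack = make_stack(frames)
        value = compute_tlasca(stack)
        assert value == pytest.approx(oracle_tlasca(frames), abs=1e-12)

    def test_zero_mean_pixel_raise_policy(self, rng):
        frames = rng.integers(1, 256, size=(5, 4, 4), dtype=np.uint8)
        frames[:, 0, 0] = 0
        with pytest.raises(ValueError, match="zero temporal mean"):
            compute_tlasca(make_stack(frames), zero_mean_policy="raise")

    def test_scale_invariance(self, rng):
        frames = rng.integers(1, 80, size=(6, 6, 6), dtype=np.uint8)
        a = compute_tlasca(make_stack(frames))
        b = compute_tlasca(make_stack(frames * 3))
        assert a == pytest.approx(b, abs=1e-12)


# -------------------------------------------------------------- inertia moment


class TestInertiaMoment:
    def test_static_video_is_zero(self, static_stack):
        assert compute_inertia_moment(static_stack) == 0.0

    def test_single_pixel_two_levels(self):
        # quantized time history (0, 1, 0) at levels=2: transitions
        # {(0,1),(1,0)} -> normalized GLCM 0.5 each -> IM = 1.0
        frames = np.array([[[10]], [[200]], [[10]]])  # bins [0,128), [128,256)
        stack = make_stack(frames)
        assert compute_inertia_moment(stack, levels=2) == pytest.approx(1.0)

    def test_two_pixel_four_levels(self):
        # pixel A levels (0,3), pixel B levels (3,3) at levels=4 ->
        # pairs {(0,3),(3,3)} -> IM = 0.5*9 + 0.5*0 = 4.5
        frames = np.array([[[10, 250]], [[250, 250]]])
        stack = make_stack(frames)
        assert compute_inertia_moment(stack, levels=4) == pytest.approx(4.5)

    def test_matches_dict_oracle(self, rng):
        for levels in (2, 8, 256):
            for _ in range(8):
                frames = rng.integers(0, 256, size=(10, 8, 8), dtype=np.uint8)
                stack = make_stack(frames)
                got = compute_inertia_moment(stack, levels=levels)
                want = oracle_inertia_moment(frames, levels, 8)
                assert got == pytest.approx(want, abs=1e-9)

    def test_default_levels_no_requantization(self, rng):
        frames = rng.integers(0, 256, size=(6, 6, 6), dtype=np.uint8)
        stack = make_stack(frames)
        assert compute_inertia_moment(stack) == compute_inertia_moment(stack, levels=256)

    def test_levels_errors(self, random_stack):
        with pytest.raises(ValueError, match="levels"):
            compute_inertia_moment(random_stack, levels=1)
        with pytest.raises(ValueError, match="exceeds"):
            compute_inertia_moment(random_stack, levels=512)

    def test_symmetric_option(self, rng):
        frames = rng.integers(0, 256, size=(6, 6, 6), dtype=np.uint8)
        stack = make_stack(frames)
        asym = compute_inertia_moment(stack, levels=8)
        sym = compute_inertia_moment(stack, levels=8, symmetric=True)
        # (i-j)^2 weight is symmetric, so symmetrization preserves IM
        assert sym == pytest.approx(asym, abs=1e-9)

    def test_scale_invariance_with_data_range_bins(self, rng):
        frames = rng.integers(0, 80, size=(6, 6, 6), dtype=np.uint8)
        a = compute_inertia_moment(make_stack(frames), levels=8, bin_range="data")
        b = compute_inertia_moment(make_stack(frames * 3), levels=8, bin_range="data")
        assert a == pytest.approx(b, abs=1e-9)


# ------------------------------------------------------------------- analyze


class TestAnalyzeStack:
    def test_static_video_partial_result(self, static_stack):
        coeffs = analyze_stack(static_stack, channel="RED")
        assert coeffs.fit is None
        assert "no measurable decay" in coeffs.fit_error
        assert coeffs.tlasca == 0.0
        assert coeffs.inertia_moment == 0.0
        assert coeffs.channel == "RED"

    def test_deterministic(self, random_stack):
        a = analyze_stack(random_stack, config=AnalysisConfig(max_lag_frames=6))
        b = analyze_stack(random_stack, config=AnalysisConfig(max_lag_frames=6))
        assert a == b

    def test_simulator_siegert_halving(self):
        from specklestress.simulate import SpeckleSimConfig, simulate_speckle_stack

        stack = simulate_speckle_stack(
            SpeckleSimConfig(n_frames=300, tau_field=0.5, beta_field=1.0, seed=11)
        )
        coeffs = analyze_stack(stack, channel="IR")
        assert coeffs.fit is not None
        assert coeffs.fit.tau == pytest.approx(0.25, rel=0.15)
        assert coeffs.tlasca > 0
        assert coeffs.inertia_moment > 0
        assert coeffs.fit.tau_star == pytest.approx(np.log(coeffs.fit.tau))

    def test_monotonic_in_field_correlation_time(self):
        from specklestress.simulate import SpeckleSimConfig, simulate_speckle_stack

        taus = []
        for tau_field in (0.2, 2.0):
            stack = simulate_speckle_stack(
                SpeckleSimConfig(n_frames=200, height=32, width=32, tau_field=tau_field, seed=5)
            )
            coeffs = analyze_stack(stack)
            taus.append(coeffs.fit.tau)
        assert taus[0] < taus[1]


# ------------------------------------------------------------------ properties


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_corr_zero_lag_always_one(seed):
    rng = np.random.default_rng(seed)
    frames = rng.integers(0, 256, size=(5, 6, 6), dtype=np.uint8)
    if any(np.ptp(f) == 0 for f in frames):  # skip degenerate draws
        return
    stack = make_stack(frames)
    curve = compute_decorrelation_curve(stack, 4)
    assert abs(curve.corr[0] - 1.0) <= 1e-12
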