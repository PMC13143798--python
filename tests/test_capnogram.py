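import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from volcap.capnogram import (
    VolumetricCapnogram,
    build_capnogram,
    fit_slope2,
    fit_slope3,
    slope3_variability,
)
from volcap.errors import (
    ContractError,
    InsufficientDataError,
    InsufficientGradientError,
    InsufficientWindowError,
)
from volcap.segmentation import BreathCycle, segment
from volcap.simulator import SimConfig, simulate

from conftest import make_series


def linear_capnogram(n=100, vt_ml=800.0, p0=20.0, slope_mmhg_per_l=8.0):
    v = np.linspace(0, vt_ml, n)
    p = p0 + slope_mmhg_per_l * v / 1000.0
    return VolumetricCapnogram(v_ml=v, pco2_mmhg=p)


class TestBuildCapnogram:
    def test_linear_construction(self):
        # constant expiratory flow 30 L/min for 1 s, PCO2 ramp 0 -> 40
        flow = np.r_[np.full(10, -30.0), np.full(100, 30.0)]
        pco2 = np.r_[np.zeros(10), np.linspace(0, 40, 100)]
        s = make_series(flow, pco2)
        cap = build_capnogram(s, BreathCycle(0, 10, 109, True))
        assert cap.vt_ml == pytest.approx(500.0)
        np.testing.assert_allclose(np.diff(cap.v_ml), 5.0, rtol=1e-12)
        np.testing.assert_allclose(cap.pco2_mmhg, np.linspace(0, 40, 100))

    def test_negative_flow_sample_clamped(self):
        flow = np.r_[np.full(5, -10.0), [10.0, 10.0, -0.2, 10.0, 10.0]]
        s = make_series(flow, np.full(10, 30.0))
        cap = build_capnogram(s, BreathCycle(0, 5, 9, True))
        assert cap.n_clamped == 1
        assert np.diff(cap.v_ml)[1] == 0.0  # zero increment at the dip
        assert np.all(np.diff(cap.v_ml) >= 0)

    def test_degenerate_expiration_rejected(self):
        s = make_series([-5, -5, -5, 5, 5])
        with pytest.raises(ContractError, match="too short"):
            build_capnogram(s, BreathCycle(0, 3, 4, True))

    def test_matches_generator_curves(self, clean_sim):
        cfg, series, truth = clean_sim
        from volcap.simulator import shapes_from_truth

        shape = shapes_from_truth(truth, cfg)[0]
        c = [c for c in segment(series) if c.complete][0]
        cap = build_capnogram(series, c)
        # analytic p(v) evaluated at the capnogram's own volumes
        expected = shape.pco2_of_volume(cap.v_ml / 1000.0)
        # one-sample discretization slack on the steep phase II
        np.testing.assert_allclose(cap.pco2_mmhg, expected, atol=1.5)
        assert cap.vt_ml == pytest.approx(truth.vt_ml.iloc[0], rel=0.005)


class TestFitSlope3:
    def test_exact_line_recovery(self):
        fit = fit_slope3(linear_capnogram(slope_mmhg_per_l=8.0))
        assert fit.slope_mmhg_per_l == pytest.approx(8.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_two_point_closed_form_oracle(self):
        # OLS on an exact line must equal the two-point slope formula
        cap = linear_capnogram(n=57, vt_ml=623.0, p0=17.3, slope_mmhg_per_l=11.7)
        fit = fit_slope3(cap)
        v = cap.v_ml / 1000.0
        p = cap.pco2_mmhg
        closed = (p[-1] - p[0]) / (v[-1] - v[0])
        assert fit.slope_mmhg_per_l == pytest.approx(closed, rel=1e-10)
        assert fit.intercept_mmhg == pytest.approx(p[0] - closed * v[0], rel=1e-10)

    def test_constant_plateau_r2_zero_convention(self):
        v = np.linspace(0, 500, 60)
        cap = VolumetricCapnogram(v_ml=v, pco2_mmhg=np.full(60, 35.0))
        with pytest.warns(UserWarning, match="zero-variance"):
            fit = fit_slope3(cap)
        assert fit.slope_mmhg_per_l == 0.0
        assert fit.r2 == 0.0

    def test_insufficient_window_carries_n_points(self):
        v = np.array([0.0, 10.0, 400.0, 1000.0])
        cap = VolumetricCapnogram(v_ml=v, pco2_mmhg=np.array([0.0, 5.0, 30.0, 35.0]))
        with pytest.raises(InsufficientWindowError) as exc:
            fit_slope3(cap)
        assert exc.value.n_points < 3

    def test_window_fidelity_and_independent_ols(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = rng.integers(50, 300)
            v = np.cumsum(rng.uniform(0, 10, n))
            p = np.clip(40 / (1 + np.exp(-(v - v[-1] * 0.2) / (v[-1] * 0.05)))
                        + rng.normal(0, 0.5, n), 0, None)
            cap = VolumetricCapnogram(v_ml=v, pco2_mmhg=p)
            try:
                fit = fit_slope3(cap)
            except InsufficientWindowError:
                continue
            mask = (v >= 0.40 * v[-1]) & (v <= 0.80 * v[-1])
            assert fit.n_points == mask.sum()
            # independent OLS oracle on exactly the in-window samples
            slope, intercept = np.polyfit(v[mask] / 1000.0, p[mask], 1)
            assert fit.slope_mmhg_per_l == pytest.approx(slope, rel=1e-9, abs=1e-9)
            assert fit.intercept_mmhg == pytest.approx(intercept, rel=1e-9, abs=1e-9)

    def test_noisy_recovery_mean_within_5pct(self):
        cfg = SimConfig(n_breaths=100, vt_ml_mean=800, vt_cv=0, time_cv=0,
                        etco2_sd=0, slope3_cv=0, slope3_mmhg_per_l_mean=10.0,
                        noise_pco2_sd_mmhg=0.3, seed=21)
        series, _ = simulate(cfg)
        slopes = np.array([
            fit_slope3(build_capnogram(series, c)).slope_mmhg_per_l
            for c in segment(series) if c.complete
        ])
        assert len(slopes) >= 99
        assert abs(slopes.mean() / 10.0 - 1) <= 0.05
        assert np.all(np.abs(slopes / 10.0 - 1) <= 0.20)

    def test_sampling_rate_invariance_5ms_vs_10ms(self):
        slopes = {}
        for dt in (5, 10):
            cfg = SimConfig(n_breaths=3, vt_cv=0, time_cv=0, etco2_sd=0,
                            slope3_cv=0, dt_ms=dt, seed=3, start_offset_ms=0.0)
            series, _ = simulate(cfg)
            c = [c for c in segment(series) if c.complete][1]
            slopes[dt] = fit_slope3(build_capnogram(series, c)).slope_mmhg_per_l
        assert abs(slopes[5] / slopes[10] - 1) < 0.01


class TestFitSlope2:
    def test_sigmoid_oracle(self):
        v = np.linspace(0, 800, 400)
        k, vstar, pmax = 0.02, 250.0, 35.0
        p = pmax / (1 + np.exp(-k * (v - vstar)))
        cap = VolumetricCapnogram(v_ml=v, pco2_mmhg=p)
        fit = fit_slope2(cap)
        g_max = pmax * k / 4 * 1000.0  # mmHg/L at the inflection
        center = (fit.lo_frac + fit.hi_frac) / 2 * cap.vt_ml
        assert abs(center - vstar) <= 2 * np.diff(v)[0]
        assert fit.slope_mmhg_per_l == pytest.approx(g_max, rel=0.10)

    def test_linear_capnogram_spans_whole_curve(self):
        cap = linear_capnogram(slope_mmhg_per_l=9.0)
        fit = fit_slope2(cap)
        assert fit.n_points == len(cap.v_ml)
        assert fit.slope_mmhg_per_l == pytest.approx(9.0, rel=1e-9)

    def test_flat_capnogram_rejected(self):
        v = np.linspace(0, 500, 50)
        cap = VolumetricCapnogram(v_ml=v, pco2_mmhg=np.full(50, 12.0))
        with pytest.raises(InsufficientGradientError):
            fit_slope2(cap)


class TestSlope3Variability:
    def test_identical_fits_cv_zero(self):
        out = slope3_variability([10.0, 10.0, 10.0])
        assert out["cv_pct"] == 0.0

    def test_hand_calculation(self):
        # slopes {8, 12}: mean 10, sample SD 2*sqrt(2), CV 28.28%
        out = slope3_variability([8.0, 12.0])
        assert out["mean"] == pytest.approx(10.0)
        assert out["sd"] == pytest.approx(2 * np.sqrt(2))
        assert out["cv_pct"] == pytest.approx(28.284271, abs=1e-5)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            slope3_variability([8.0])

    def test_generator_jitter_recovered(self):
        cvs = []
        for seed in (1, 2, 3):
            cfg = SimConfig(n_breaths=50, slope3_cv=0.30, vt_cv=0.05,
                            time_cv=0.03, etco2_sd=0.3, seed=seed)
            series, _ = simulate(cfg)
            fits = [fit_slope3(build_capnogram(series, c))
                    for c in segment(series) if c.complete]
            cvs.append(slope3_variability(fits)["cv_pct"])
        assert all(20.0 <= cv <= 40.0 for cv in cvs)


@given(slope=st.floats(1.0, 30.0), vt=st.floats(300.0, 1200.0),
       p0=st.floats(5.0, 30.0))
@settings(max_examples=40, deadline=None)
def test_slope3_exact_on_random_lines(slope, vt, p0):
    cap = linear_capnogram(n=120, vt_ml=vt, p0=p0, slope_mmhg_per_l=slope)
    fit = fit_slope3(cap)
    assert fit.slope_mmhg_per_l == pytest.approx(slope, rel=1e-8)
    assert fit.r2 == pytest.approx(1.0, abs=1e-9)
    # normalized slope convention: slope * VT / mean window PCO2
    mask = (cap.v_ml >= 0.4 * vt) & (cap.v_ml <= 0.8 * vt)
    expected_norm = slope * (vt / 1000.0) / cap.pco2_mmhg[mask].mean()
    assert fit.normalized_slope == pytest.approx(expected_norm, rel=1e-8)
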