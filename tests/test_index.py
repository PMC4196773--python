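"""Two-line characterisation, phi angle, standardisation, end-to-end mfARI."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mfari.errors import InsufficientDataError
from mfari.index import (
    Config,
    MfariParams,
    StandardisationModel,
    abp_recovery_line,
    fit_standardisation,
    measure_template_params,
    mfari_from_manoeuvre,
    phi_angle,
    published_model,
    standardise,
    two_line_fit,
)
from mfari.preprocess import Manoeuvre, NormalisedResponse, normalise_drop
from mfari.synthetic import SimSpec, simulate_manoeuvre

RATE = 5.0


def _response(values, t_min):
    values = np.asarray(values, dtype=float)
    return NormalisedResponse(
        values=values, rate=RATE, t0=4.0, t_min=t_min,
        baseline=1.0, drop_amplitude=1.0,
    )


def _ramp_response(ramp_s=3.0, level=0.9, total_s=26.0, t_min=4.0):
    """0 until t_min, linear ramp to ``level`` over ``ramp_s``, then flat."""
    n = int(total_s * RATE) + 1
    t = np.arange(n) / RATE
    x = np.where(t < t_min, 1.0, 0.0)  # baseline segment (pre-drop)
    post = t >= t_min
    x[post] = np.minimum((t[post] - t_min) / ramp_s, 1.0) * level
    x[t < t_min] = 1.0
    return _response(x, t_min)


def naive_two_line_scan(resp, cfg):
    """Independent brute-force reimplementation using polyfit per segment."""
    x, rate = resp.values, resp.rate
    i_min = int(round(resp.t_min * rate))
    t = np.arange(x.size) / rate
    n_steady = int(round(cfg.dt_steady * rate))
    candidates = []
    for j in range(i_min + max(1, int(round(cfg.tau_min_offset * rate))),
                   i_min + int(round(cfg.tau_max_offset * rate)) + 1):
        seg_t, seg_x = t[i_min : j + 1], x[i_min : j + 1]
        coef = np.polyfit(seg_t, seg_x, 1)
        err_t = seg_x - np.polyval(coef, seg_t)
        steady = x[j + 1 : j + 1 + n_steady]
        err_s = steady - x[j]
        mse = (np.sum(err_t**2) + np.sum(err_s**2)) / (len(seg_t) + len(steady))
        candidates.append((mse, j))
    best_mse = min(c[0] for c in candidates)
    tied = [j for mse, j in candidates if mse == best_mse]
    j = max(tied) if cfg.tie_break == "largest" else min(tied)
    return j / rate, (j - i_min) / rate, float(x[j])


class TestTwoLineFit:
    def test_exact_breakpoint_on_piecewise_linear_input(self):
        fit = two_line_fit(_ramp_response())
        assert fit.tau_star == pytest.approx(7.0)
        assert fit.delta_tau == pytest.approx(3.0)
        assert fit.k_s == pytest.approx(0.9)
        assert fit.mse == pytest.approx(0.0, abs=1e-18)
        assert fit.transient_slope == pytest.approx(0.3)

    def test_too_short_response_rejected(self):
        with pytest.raises(InsufficientDataError):
            two_line_fit(_ramp_response(total_s=12.0))

    @pytest.mark.parametrize("tie_break", ["smallest", "largest"])
    def test_matches_naive_exhaustive_scan(self, tie_break, rng):
        cfg = Config(tie_break=tie_break)
        for _ in range(100):
            # random smooth response: filtered noise settling after a ramp
            raw = rng.normal(0, 1.0, 140)
            smooth = np.convolve(raw, np.ones(9) / 9, mode="same")
            x = np.concatenate([np.full(20, 1.0), np.zeros(120)])
            ramp = 1 - np.exp(-np.arange(120) / (2 + 10 * rng.random()))
            x[20:] = ramp * (0.5 + 0.5 * rng.random()) + 0.08 * smooth[20:]
            resp = _response(x, t_min=4.0)
            fit = two_line_fit(resp, cfg)
            tau, dtau, k_s = naive_two_line_scan(resp, cfg)
            assert fit.tau_star == tau
            assert fit.delta_tau == dtau
            assert fit.k_s == k_s

    def test_flat_response_tie_break_direction(self):
        flat = _response(np.concatenate([np.ones(20), np.zeros(120)]), t_min=4.0)
        assert two_line_fit(flat, Config(tie_break="largest")).delta_tau == 10.0
        assert two_line_fit(flat, Config(tie_break="smallest")).delta_tau == 0.4


class TestAbpRecoveryLine:
    def test_sustained_step_has_zero_slope(self):
        x = np.concatenate([np.ones(20), np.zeros(120)])
        slope, _ = abp_recovery_line(_response(x, t_min=4.0))
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_linear_recovery_slope(self):
        # recovery of 0.25/s from the minimum: 0 -> 0.5 over the 2 s segment
        x = np.concatenate([np.ones(20), 0.25 * np.arange(121) / RATE])
        slope, seg = abp_recovery_line(_response(x, t_min=4.0))
        assert slope == pytest.approx(0.25)
        assert seg.stop - seg.start == int(2.0 * RATE) + 1

    def test_minimum_search_window_ignores_later_dip(self):
        x = np.full(100, 100.0)
        x[27] = 70.0   # dip at 1.4 s post-release
        x[35] = 50.0   # deeper dip at 3 s: outside the 2 s ABP search window
        resp = normalise_drop(x, RATE, t0=4.0, search_window=2.0)
        assert resp.t_min == pytest.approx(27 / RATE)


class TestPhiAngle:
    def test_equal_slopes_cancel(self):
        assert phi_angle(0.4, 0.4) == pytest.approx(0.0)

    def test_unit_slope_against_flat_pressure(self):
        assert phi_angle(1.0, 0.0) == pytest.approx(45.0)

    def test_negative_slopes_clamp_at_zero(self):
        assert phi_angle(-0.3, 0.0) == pytest.approx(0.0)
        assert phi_angle(1.0, -1.0) == pytest.approx(45.0)


def _hand_ols(X, y):
    Xd = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(Xd.T @ Xd, Xd.T @ y)


class TestStandardisation:
    def test_regression_matches_hand_normal_equations(self, templates, std_model):
        X = measure_template_params(templates)
        coef = _hand_ols(X, templates.ari_values)
        assert np.allclose(std_model.coef, coef, atol=1e-8)

    def test_r2_high_and_bounds_from_templates(self, templates, std_model):
        assert 0.99 <= std_model.r2 <= 1.0
        X = measure_template_params(templates)
        assert std_model.bounds["k_s"] == (X[:, 0].min(), X[:, 0].max())
        assert std_model.bounds["delta_tau"][0] == pytest.approx(1.2)
        assert std_model.bounds["delta_tau"][1] == pytest.approx(10.0)

    def test_exactly_linear_target_recovered_perfectly(self):
        # a response vector that IS linear in the parameters: R^2 = 1 and
        # the hand normal equations return the generating coefficients
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 1, (40, 3)) * [1.0, 10.0, 40.0]
        y = 1.5 + 2.0 * X[:, 0] - 0.1 * X[:, 1] + 0.05 * X[:, 2]
        coef = _hand_ols(X, y)
        assert np.allclose(coef, [1.5, 2.0, -0.1, 0.05])

    def test_toy_design_matches_numpy_lstsq(self):
        X = np.array([[0.0, 10.0, 0.0], [0.5, 6.0, 5.0],
                      [0.9, 3.0, 20.0], [1.0, 1.5, 35.0]])
        y = np.array([0.3, 3.0, 6.5, 9.0])
        coef = _hand_ols(X, y)
        ref, *_ = np.linalg.lstsq(np.column_stack([np.ones(4), X]), y, rcond=None)
        assert np.allclose(coef, ref)

    def test_published_coefficients_evaluate_known_points(self):
        model = published_model()
        # fully impaired: k_S=0, longest transient, no angle separation
        lo = standardise(MfariParams(0.0, 10.0, 0.0), model)
        assert lo == pytest.approx(1.631 - 1.37, abs=1e-9)
        # best response at the published parameter maxima: clipped at 9
        hi = standardise(MfariParams(1.07, 1.2, 37.87), model)
        assert hi == 9.0
        # all-zero parameters clamp delta_tau to its lower bound first
        mid = standardise(MfariParams(0.0, 0.0, 0.0), model)
        assert mid == pytest.approx(1.631 - 0.137 * 1.2, abs=1e-9)

    def test_model_json_round_trip_is_bit_exact(self, std_model, tmp_path):
        path = tmp_path / "model.json"
        std_model.to_json(path)
        back = StandardisationModel.from_json(path)
        assert back.coef == std_model.coef
        assert back.bounds == std_model.bounds
        assert back.r2 == std_model.r2
        assert back.tvalues == std_model.tvalues


class TestEndToEnd:
    def test_template_self_consistency(self, templates, std_model):
        X = measure_template_params(templates)
        errs = [
            standardise(MfariParams(*row), std_model) - ari
            for row, ari in zip(X, templates.ari_values)
        ]
        errs = np.asarray(errs)
        assert np.sqrt(np.mean(errs**2)) <= 0.15
        assert np.abs(errs).max() <= 0.5

    def test_noiseless_step_recovers_generating_grade(self, std_model):
        value, params, diag = mfari_from_manoeuvre(
            simulate_manoeuvre(SimSpec(ari_true=5.0)), std_model
        )
        assert value == pytest.approx(5.0, abs=0.35)
        assert diag["two_line_fit"].delta_tau == params.delta_tau

    def test_passive_flow_scores_below_one(self, std_model):
        abp = np.concatenate([np.full(25, 90.0), np.full(126, 70.0)])
        cbfv = 55.0 * abp / 90.0
        m = Manoeuvre(abp=abp, cbfv=cbfv, rate=5.0, t0=5.0)
        value, params, _ = mfari_from_manoeuvre(m, std_model)
        assert value < 1.0
        assert params.k_s == pytest.approx(0.0, abs=1e-9)

    def test_short_recording_rejected_with_channel_identity(self, std_model):
        m = simulate_manoeuvre(SimSpec(ari_true=5.0))
        short = Manoeuvre(abp=m.abp[:40], cbfv=m.cbfv[:40], rate=5.0, t0=5.0)
        with pytest.raises(InsufficientDataError):
            mfari_from_manoeuvre(short, std_model)

    @given(
        gain_a=st.floats(0.2, 5.0), gain_c=st.floats(0.2, 5.0),
        off_a=st.floats(-20.0, 20.0), off_c=st.floats(-10.0, 10.0),
    )
    def test_invariant_to_channel_scale_and_offset(self, gain_a, gain_c, off_a, off_c):
        model = published_model()
        m = simulate_manoeuvre(SimSpec(ari_true=4.0))
        ref, _, _ = mfari_from_manoeuvre(m, model)
        m2 = Manoeuvre(
            abp=gain_a * m.abp + off_a, cbfv=gain_c * m.cbfv + off_c,
            rate=m.rate, t0=m.t0,
        )
        got, _, _ = mfari_from_manoeuvre(m2, model)
        assert got == pytest.approx(ref, abs=1e-9)

    def test_step_template_phi_equals_transient_angle(self, templates):
        cfg = Config()
        for resp in templates.responses[::10]:
            fit = two_line_fit(resp, cfg)
            phi = phi_angle(fit.transient_slope, 0.0)
            assert phi >= 0.0
            expected = max(np.degrees(np.arctan(fit.transient_slope)), 0.0)
            assert phi == pytest.approx(expected)
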