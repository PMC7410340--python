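"""Rate-tier dynamics: gain function, depression, inputs, integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acxsim.params import RateParams
from acxsim.protocols import ToneProtocol, Tone, make_oddball, make_single_tone
from acxsim.rate import (
    RateState,
    baseline_facilitation_trajectory,
    fbar_asymptote,
    lateral_terms,
    select_regime,
    simulate_rate,
    single_unit_rhs,
    thalamic_depression_rhs,
    threshold_linear,
    tone_input_trace,
)


class TestThresholdLinear:
    @pytest.mark.parametrize("x,r,theta,expected", [
        (-1.0, 3.0, 0.0, 0.0),   # below threshold
        (10.0, 3.0, 0.0, 1.0),   # saturated
        (0.9, 3.0, 0.7, 0.6),    # linear segment: 3 * (0.9 - 0.7)
        (0.7, 3.0, 0.7, 0.0),    # exactly at threshold
        (0.7 + 1 / 3, 3.0, 0.7, 1.0),  # knee of the saturation
    ])
    def test_values(self, x, r, theta, expected):
        assert threshold_linear(x, r, theta) == pytest.approx(expected)

    @settings(max_examples=50, derandomize=True)
    @given(x=st.floats(-10, 10), r=st.floats(0.1, 10), theta=st.floats(-2, 2))
    def test_bounded_and_monotone(self, x, r, theta):
        y = threshold_linear(x, r, theta)
        assert 0.0 <= y <= 1.0
        assert threshold_linear(x + 0.5, r, theta) >= y

    def test_rejects_nonfinite_and_bad_gain(self):
        with pytest.raises(ValueError):
            threshold_linear(np.nan)
        with pytest.raises(ValueError):
            threshold_linear(0.0, r=0.0)


class TestThalamicDepression:
    def test_baseline_fixed_point(self):
        p = RateParams()
        assert thalamic_depression_rhs(1.0, 0.0, p) == 0.0

    def test_closed_form_values(self):
        p = RateParams()
        assert thalamic_depression_rhs(0.5, 0.0, p) == pytest.approx(0.5 / 1500.0)
        assert thalamic_depression_rhs(1.0, 1.0, p) == pytest.approx(
            -1.0 / 20.0
        )

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            thalamic_depression_rhs(1.0, -0.5, RateParams())


class TestToneInputTrace:
    def test_empty_protocol_is_zero(self):
        prot = ToneProtocol([], span=1000.0)
        t = np.linspace(0, 999, 1000)
        assert not tone_input_trace(prot, 1, t).any()

    def test_single_tone_is_exponential(self):
        prot = ToneProtocol([Tone(0.0, 100.0, 0)], span=1000.0)
        t = np.linspace(0.0, 200.0, 2001)
        trace = tone_input_trace(prot, 0, t)
        assert np.allclose(trace, np.exp(-t / 10.0), atol=1e-12)

    def test_cross_unit_spread_is_alpha_scaled(self):
        prot = ToneProtocol([Tone(50.0, 100.0, 0)], span=1000.0)
        t = np.linspace(0.0, 500.0, 501)
        own = tone_input_trace(prot, 0, t)
        center = tone_input_trace(prot, 1, t, alpha=0.65)
        far = tone_input_trace(prot, 2, t, alpha=0.65)
        assert np.allclose(center, 0.65 * own)
        # the opposite edge is two steps away and receives nothing
        assert not far.any()


class TestSingleUnitRhs:
    def test_origin_is_fixed_point(self):
        p = RateParams()
        state = RateState.initial(1)
        d = single_unit_rhs(state, 0.0, (0.0, 0.0), p)
        assert d.u[0] == d.p[0] == d.s[0] == d.g[0] == 0.0

    def test_single_row_evaluation(self):
        # drive q*g*i = 1.0 against threshold 0.7 with gain 3:
        # du = f(0.3)/tau_u = 0.9 / 10
        p = RateParams()
        state = RateState.initial(1)
        d = single_unit_rhs(state, 1.0 / p.q, (0.0, 0.0), p)
        assert d.u[0] == pytest.approx(0.09)

    def test_strong_sst_suppression_decays_sst(self):
        p = RateParams()
        state = RateState.initial(1)
        state.s[0] = 0.5
        d = single_unit_rhs(state, 0.0, (0.0, -10.0), p)
        assert d.s[0] == pytest.approx(-0.05)  # pure decay -s/tau_s


class TestLateralTerms:
    def test_zero_state_gives_zero(self, three_unit_params):
        z = np.zeros(3)
        assert lateral_terms(0, z, z, z, z, three_unit_params) == (0.0, 0.0, 0.0)

    def test_center_receives_edge_mean(self, three_unit_params):
        u = np.array([0.3, 0.0, 0.3])
        z = np.zeros(3)
        J1, J2, J3 = lateral_terms(1, u, z, z, z, three_unit_params)
        assert J1 == pytest.approx(0.667 * 0.3)
        assert J2 == pytest.approx(1.25 * 0.3)
        assert J3 == pytest.approx(0.125 * 0.3)

    def test_edge_receives_center(self, three_unit_params):
        u = np.array([0.0, 0.4, 0.0])
        z = np.zeros(3)
        _, _, J3 = lateral_terms(2, u, z, z, z, three_unit_params)
        assert J3 == pytest.approx(0.125 * 0.4)

    def test_requires_three_units(self, three_unit_params):
        z = np.zeros(2)
        with pytest.raises(ValueError):
            lateral_terms(0, z, z, z, z, three_unit_params)


class TestBaselineFacilitation:
    def test_zero_input_stays_zero(self, three_unit_params):
        prot = ToneProtocol([], span=2000.0)
        _, fbar = baseline_facilitation_trajectory(prot, three_unit_params)
        assert not fbar.any()

    def test_constant_drive_steady_state(self, three_unit_params):
        # dF/dt = -F^2/tau1 + c/tau2 = 0  =>  F* = sqrt(c tau1 / tau2).
        # Emulate constant drive with a dense tone train whose mean input
        # is c = tau_q / period.
        period = 20.0
        tones = [Tone(k * period, 10.0, 0) for k in range(1500)]
        prot = ToneProtocol(tones, span=1500 * period)
        t, fbar = baseline_facilitation_trajectory(prot, three_unit_params)
        c = 10.0 / period  # tone kernel integral tau_q per period
        expected = np.sqrt(c * 1500.0 / 100.0)
        assert fbar[t > 20000].mean() == pytest.approx(expected, rel=0.05)

    def test_oddball_asymptote_is_above_threshold(self, three_unit_params):
        prot = make_oddball(n_tones=100, seed=0)
        assert fbar_asymptote(prot, three_unit_params) > 0.22


class TestSelectRegime:
    def test_weak_above_threshold(self, three_unit_params):
        reg = select_regime(0.5, three_unit_params)
        assert reg.name == "weak"
        assert reg.W[0, 1] == 2.0 and reg.W[0, 2] == 1.0 and reg.s_th == 1.0

    def test_strong_below_threshold(self, three_unit_params):
        reg = select_regime(0.1, three_unit_params)
        assert reg.name == "strong"
        assert reg.W[0, 1] == 3.0 and reg.W[0, 2] == 3.0 and reg.s_th == 0.0

    def test_tie_classified_weak(self, three_unit_params):
        assert select_regime(0.22, three_unit_params).name == "weak"

    def test_smooth_midpoint(self, three_unit_params):
        reg = select_regime(0.22, three_unit_params, smooth=True)
        assert reg.W[0, 1] == pytest.approx(2.5)
        assert reg.W[0, 2] == pytest.approx(2.0)
        assert reg.s_th == pytest.approx(0.5)

    def test_negative_rejected(self, three_unit_params):
        with pytest.raises(ValueError):
            select_regime(-0.1, three_unit_params)


class TestSimulateRate:
    def test_zero_input_fixed_point_10s(self, three_unit_params):
        prot = ToneProtocol([], span=10_000.0)
        traj = simulate_rate(three_unit_params, prot, record_every=100)
        for arr in (traj.u, traj.p, traj.s):
            assert np.abs(arr).max() == 0.0
        assert np.allclose(traj.g, 1.0)

    def test_boundedness(self, three_unit_params):
        prot = make_oddball(n_tones=30, seed=2)
        traj = simulate_rate(three_unit_params, prot, record_every=10)
        for arr in (traj.u, traj.p, traj.s):
            assert arr.min() >= 0.0 and arr.max() <= 1.0
        assert traj.g.min() > 0.0 and traj.g.max() <= 1.0

    def test_rk4_matches_fine_euler(self, three_unit_params):
        tones = [Tone(100.0, 100.0, 0), Tone(500.0, 100.0, 2)]
        prot = ToneProtocol(tones, span=1000.0, paradigm="test")
        coarse = simulate_rate(three_unit_params, prot, dt=0.1, record_every=10)
        fine = simulate_rate(three_unit_params, prot, dt=0.001,
                             record_every=1000, method="euler")
        err = np.abs(coarse.u - fine.u).max()
        assert err < 1e-3

    def test_rk4_dt_convergence(self, three_unit_params):
        # the threshold-linear gain is only piecewise-smooth, so step
        # halving converges at reduced order near threshold crossings;
        # 1e-4 absolute on activities in [0, 1] is the realistic bound
        prot = ToneProtocol([Tone(50.0, 100.0, 1)], span=500.0)
        a = simulate_rate(three_unit_params, prot, dt=0.1, record_every=10)
        b = simulate_rate(three_unit_params, prot, dt=0.05, record_every=20)
        assert np.abs(a.u - b.u).max() < 1e-4

    def test_pv_peaks_before_sst_single_unit(self):
        # PVs receive direct thalamic drive; SSTs only via Exc, so the SST
        # response is delayed relative to PV.
        p = RateParams(q=5.0)
        prot = ToneProtocol([Tone(100.0, 100.0, 0)], span=600.0)
        traj = simulate_rate(p, prot, n_units=1, record_every=10)
        t_pv = traj.time_ms[np.argmax(traj.p[0])]
        t_sst = traj.time_ms[np.argmax(traj.s[0])]
        assert t_pv < t_sst

    def test_current_decomposition_identity(self, three_unit_params):
        prot = make_single_tone(unit=1, n_trials=1)
        traj = simulate_rate(three_unit_params, prot, regime="strong",
                             record_every=10)
        exc, inh = traj.exc_drive_decomposition(1)
        # both components nonnegative; the peak drive is excitation-led
        assert exc.min() >= 0 and inh.min() >= 0
        assert exc.max() > inh.max() * 0.1

    def test_adaptation_direction_8_tones(self):
        # mean Exc response is non-increasing across 8 repeated tones
        p = RateParams(q=5.0)
        tones = [Tone(100.0 + 400.0 * k, 100.0, 0) for k in range(8)]
        prot = ToneProtocol(tones, span=3700.0)
        traj = simulate_rate(p, prot, n_units=1, record_every=10)
        resp = [
            traj.u[0][(traj.time_ms >= t.onset)
                      & (traj.time_ms < t.onset + t.duration)].mean()
            for t in tones
        ]
        assert all(a >= b - 1e-9 for a, b in zip(resp, resp[1:]))

    def test_pv_compensation_for_sst_loss(self):
        """On tone 1, total inhibitory current into Exc under SST
        suppression stays within 10% of control (PVs compensate), while PV
        suppression removes more than 10% of it."""
        p = RateParams(q=5.0)
        tones = [Tone(200.0, 100.0, 0)]
        prot = ToneProtocol(tones, span=600.0)

        def inh_peak(opto):
            from acxsim.protocols import OptoSchedule
            scheds = []
            for target, amp in opto.items():
                scheds.append(OptoSchedule(
                    target=target, amplitude=amp, mode="tone_locked",
                    windows=[[100.0, 400.0]],
                ))
            traj = simulate_rate(p, prot, opto=scheds, n_units=1,
                                 record_every=10)
            exc, inh = traj.exc_drive_decomposition(0)
            win = (traj.time_ms >= 200.0) & (traj.time_ms < 330.0)
            return inh[win].max()

        control = inh_peak({})
        sst_sup = inh_peak({"sst": -1.0})
        pv_sup = inh_peak({"pv": -2.0})
        assert abs(sst_sup - control) / control < 0.10
        assert (control - pv_sup) / control > 0.10

    def test_invalid_arguments(self, three_unit_params):
        prot = make_single_tone(unit=1)
        with pytest.raises(ValueError):
            simulate_rate(three_unit_params, prot, dt=0.0)
        with pytest.raises(ValueError):
            simulate_rate(three_unit_params, prot, method="rk2")
        with pytest.raises(ValueError):
            simulate_rate(three_unit_params, prot, n_units=2)
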