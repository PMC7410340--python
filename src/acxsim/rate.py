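"""Wilson-Cowan rate tier: one iso-frequency unit and the three-unit tonotopy.

The unit dynamics are

    tau_u du/dt = -u + f(w_ee u - w_ep p - w_es s + q g(t) i(t) - u_th)
    tau_p dp/dt = -p + f(w_pe u - w_pp p - w_ps s + I_opt,PV + q g(t) i(t) - p_th)
    tau_s ds/dt = -s + f(w_se u + I_opt,SST - s_th)

with the saturating threshold-linear gain f, thalamic input i(t)
(instantaneous rise, exponential decay, tau_q = 10 ms) gated by the slow
depression resource g(t).  The three-unit model adds lateral excitation
(Exc -> Exc/PV/SST of the neighbors), a facilitating lateral SST -> Exc
synapse, a depressing PV -> Exc synapse, thalamic cross-unit spread
(fraction alpha), and a slow baseline-facilitation variable Fbar whose
asymptote selects the weak or strong baseline-inhibition regime.

Integration is fixed-step classical RK4 at dt = 0.1 ms (an explicit-Euler
path is kept as an accuracy oracle).  Tone onsets are applied as exact
jumps of the input state on the step grid; the input decays analytically
within a step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import RateParams, ThreeUnitRateParams, W_STRONG, W_WEAK
from .protocols import OptoSchedule, ToneProtocol
from .results import Trajectory

__all__ = [
    "threshold_linear",
    "thalamic_depression_rhs",
    "tone_input_trace",
    "RateState",
    "single_unit_rhs",
    "lateral_terms",
    "baseline_facilitation_trajectory",
    "select_regime",
    "Regime",
    "simulate_rate",
]


# ---------------------------------------------------------------------------
# Elementary pieces
# ---------------------------------------------------------------------------

@njit(cache=True)
def _f(x: float, r: float) -> float:
    if x <= 0.0:
        return 0.0
    y = r * x
    return y if y < 1.0 else 1.0


def threshold_linear(x, r: float = 3.0, theta: float = 0.0):
    """Saturating threshold-linear gain: f(x - theta), clipped to [0, 1].

    f(y) = 0 for y <= 0, r*y for 0 < y <= 1/r, and 1 beyond.
    """
    if r <= 0:
        raise ValueError("gain r must be positive")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input to threshold_linear")
    out = np.clip(r * (x - theta), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def thalamic_depression_rhs(g: float, i: float, params: RateParams) -> float:
    """dg/dt of the thalamic depression resource (per ms)."""
    if i < 0:
        raise ValueError("thalamic input must be nonnegative")
    return (params.g0 - g) / params.tau_d1 - g * i / params.tau_d2


def tone_input_trace(
    protocol: ToneProtocol,
    unit: int,
    time_ms: np.ndarray,
    tau_q: float = 10.0,
    alpha: float | None = None,
) -> np.ndarray:
    """Thalamic input trace reaching ``unit`` on a time grid.

    Each tone contributes a unit-amplitude jump at onset with exponential
    decay (tau_q).  With ``alpha`` given, tones addressed to adjacent units
    contribute a fraction alpha of their trace (edge units see the center,
    the center sees both edges), mirroring the cross-unit thalamic spread.
    Without ``alpha`` only the unit's own tones contribute (this is the
    trace that drives the unit's depression variable).
    """
    time_ms = np.asarray(time_ms, dtype=float)
    out = np.zeros_like(time_ms)
    for tone in protocol.tones:
        if tone.unit == unit:
            w = tone.amplitude
        elif alpha is not None and abs(tone.unit - unit) == 1:
            w = alpha * tone.amplitude
        else:
            continue
        m = time_ms >= tone.onset
        out[m] += w * np.exp(-(time_ms[m] - tone.onset) / tau_q)
    return out


@dataclass
class RateState:
    """State of the rate model: arrays of shape (n_units,) plus scalar Fbar."""

    u: np.ndarray
    p: np.ndarray
    s: np.ndarray
    g: np.ndarray
    F: np.ndarray
    D: np.ndarray
    Fbar: float = 0.0

    @classmethod
    def initial(cls, n_units: int) -> "RateState":
        z = np.zeros(n_units)
        return cls(
            u=z.copy(), p=z.copy(), s=z.copy(),
            g=np.ones(n_units), F=z.copy(), D=np.ones(n_units), Fbar=0.0,
        )


def single_unit_rhs(
    state: RateState,
    drive: float,
    opto: tuple[float, float],
    params: RateParams,
) -> RateState:
    """Time derivative of the single-unit model (Eq-level reference path).

    ``drive`` is the raw thalamic input i(t); it enters Exc and PV as
    q * g * i.  ``opto`` is (I_opt_PV, I_opt_SST).  Returns a RateState of
    derivatives (g0 baseline recovery included; F, D, Fbar unused here).
    """
    W = params.W
    u, p, s, g = state.u[0], state.p[0], state.s[0], state.g[0]
    i_pv, i_sst = opto
    thal = params.q * g * drive
    du = (-u + threshold_linear(
        W[0, 0] * u - W[0, 1] * p - W[0, 2] * s + thal, params.r, params.u_th
    )) / params.tau_u
    dp = (-p + threshold_linear(
        W[1, 0] * u - W[1, 1] * p - W[1, 2] * s + i_pv + thal,
        params.r, params.p_th,
    )) / params.tau_p
    ds = (-s + threshold_linear(
        W[2, 0] * u + i_sst, params.r, params.s_th
    )) / params.tau_s
    dg = thalamic_depression_rhs(g, drive, params)
    return RateState(
        u=np.array([du]), p=np.array([dp]), s=np.array([ds]),
        g=np.array([dg]), F=np.zeros(1), D=np.zeros(1), Fbar=0.0,
    )


def lateral_terms(
    unit: int,
    u: np.ndarray,
    s: np.ndarray,
    F: np.ndarray,
    inputs: np.ndarray,
    params: ThreeUnitRateParams,
) -> tuple[float, float, float]:
    """Lateral contributions (J1, J2, J3) to the Exc, PV, SST drive of ``unit``.

    ``inputs`` are the mixed thalamic inputs I_k(t) (depression-gated,
    alpha-spread).  Edge units receive from the center; the center receives
    the mean of the two edges for the excitatory terms and the sum of the
    edge SST activities for the facilitating inhibitory term, exactly as the
    model equations are written.
    """
    if len(u) != 3:
        raise ValueError("lateral terms are defined for exactly 3 units")
    q = params.base.q
    b = params.b_fac
    if unit in (0, 2):
        lat_u = u[1]
        sst_term = b * F[unit] * s[1]
    elif unit == 1:
        lat_u = 0.5 * (u[0] + u[2])
        sst_term = b * F[1] * (s[0] + s[2])
    else:
        raise ValueError("unit index must be 0, 1 or 2")
    J1 = -sst_term + q * inputs[unit] + params.w_ee_lat * lat_u
    J2 = q * inputs[unit] + params.w_pe_lat * lat_u
    J3 = params.w_se_lat * lat_u
    return J1, J2, J3


# ---------------------------------------------------------------------------
# Regime selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Regime:
    name: str  # "weak" | "strong" | "smooth"
    W: np.ndarray
    s_th: float


def baseline_facilitation_trajectory(
    protocol: ToneProtocol,
    params: ThreeUnitRateParams,
    dt: float = 1.0,
    span: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the baseline facilitation dFbar/dt = -Fbar^2/tau_F1 + Ibar/tau_F2.

    Ibar(t) sums the raw thalamic input traces of all units regardless of
    frequency.  Returns (time grid, Fbar trace); Fbar(0) = 0.
    """
    span = protocol.span if span is None else span
    time = np.arange(0.0, span + dt / 2, dt)
    ibar = np.zeros_like(time)
    for u in range(3):
        ibar += tone_input_trace(protocol, u, time, tau_q=params.base.tau_q)
    fbar = np.zeros_like(time)
    # RK4 with linear interpolation of Ibar at half-steps
    for k in range(len(time) - 1):
        f0, i0 = fbar[k], ibar[k]
        ih = 0.5 * (ibar[k] + ibar[k + 1])
        i1 = ibar[k + 1]
        rhs = lambda F, I: -F * F / params.tau_F1 + I / params.tau_F2
        k1 = rhs(f0, i0)
        k2 = rhs(f0 + 0.5 * dt * k1, ih)
        k3 = rhs(f0 + 0.5 * dt * k2, ih)
        k4 = rhs(f0 + dt * k3, i1)
        fbar[k + 1] = f0 + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return time, fbar


def fbar_asymptote(
    protocol: ToneProtocol,
    params: ThreeUnitRateParams,
    span: float = 30000.0,
    tail: float = 5000.0,
) -> float:
    """Fbar asymptote: mean of Fbar over the last ``tail`` ms of a 30 s run."""
    time, fbar = baseline_facilitation_trajectory(protocol, params, span=span)
    return float(fbar[time >= span - tail].mean())


def select_regime(
    fbar_asymptote: float,
    params: ThreeUnitRateParams,
    smooth: bool = False,
) -> Regime:
    """Map the Fbar asymptote to the baseline-inhibition regime.

    At or above F_th: weak inhibition (W_WEAK, s_th = 1); below: strong
    inhibition (W_STRONG, s_th = 0).  With ``smooth=True`` the inhibitory
    weights onto Exc and the SST threshold blend sigmoidally:
    w_ep = 2h + 3(1-h), w_es = h + 3(1-h), s_th = h, with
    h = 1 / (1 + exp(-h_gain (Fbar - F_th))).
    """
    if fbar_asymptote < 0:
        raise ValueError("Fbar asymptote must be nonnegative")
    base_W = params.base.W
    if smooth:
        h = 1.0 / (1.0 + np.exp(-params.h_gain * (fbar_asymptote - params.F_th)))
        W = base_W.copy()
        W[0, 1] = W_WEAK[0, 1] * h + W_STRONG[0, 1] * (1.0 - h)
        W[0, 2] = W_WEAK[0, 2] * h + W_STRONG[0, 2] * (1.0 - h)
        return Regime("smooth", W, float(h))
    if fbar_asymptote >= params.F_th:
        return Regime("weak", base_W.copy(), params.base.s_th)
    W = base_W.copy()
    W[0, 1] = W_STRONG[0, 1]
    W[0, 2] = W_STRONG[0, 2]
    return Regime("strong", W, params.s_th_strong)


def regime_for(
    preset_or_regime: str,
    protocol: ToneProtocol | None = None,
    params: ThreeUnitRateParams | None = None,
) -> Regime:
    """Resolve a regime name ("weak"/"strong") or "auto" (Fbar threshold)."""
    params = params or ThreeUnitRateParams()
    if preset_or_regime == "weak":
        return select_regime(params.F_th, params)
    if preset_or_regime == "strong":
        return select_regime(0.0, params)
    if preset_or_regime == "auto":
        if protocol is None:
            raise ValueError("auto regime needs a protocol")
        return select_regime(fbar_asymptote(protocol, params), params)
    raise ValueError(f"unknown regime {preset_or_regime!r}")


# ---------------------------------------------------------------------------
# Integration kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _opto_val(t, windows, amp, idx):
    """Piecewise-constant opto value at time t; windows sorted & disjoint."""
    n = windows.shape[0]
    while idx < n and t >= windows[idx, 1]:
        idx += 1
    if idx < n and windows[idx, 0] <= t:
        return amp, idx
    return 0.0, idx


@njit(cache=True)
def _rhs3(y, iv, pv_val, sst_val,
          wee, wep, wes, wpe, wpp, wps, wse,
          u_th, p_th, s_th, r, tau_u, tau_p, tau_s,
          q, tau_d1, tau_d2, g0,
          wee_l, wpe_l, wse_l, alpha, a_dep, b_fac,
          tau_F1, tau_F2, F_th, h_gain, smooth, use_proxies,
          dy):
    u0, u1, u2 = y[0], y[1], y[2]
    p0, p1, p2 = y[3], y[4], y[5]
    s0, s1, s2 = y[6], y[7], y[8]
    g = y[9:12]
    Fbar = y[18]

    if smooth:
        h = 1.0 / (1.0 + np.exp(-h_gain * (Fbar - F_th)))
        wep_t = 2.0 * h + 3.0 * (1.0 - h)
        wes_t = h + 3.0 * (1.0 - h)
        s_th_t = h
    else:
        wep_t, wes_t, s_th_t = wep, wes, s_th

    gi0 = g[0] * iv[0]
    gi1 = g[1] * iv[1]
    gi2 = g[2] * iv[2]
    # mixed thalamic inputs with cross-unit spread
    I0 = gi0 + alpha * gi1
    I1 = alpha * (gi0 + gi2) + gi1
    I2 = gi2 + alpha * gi1

    us = (u0, u1, u2)
    ps = (p0, p1, p2)
    ss = (s0, s1, s2)
    Is = (I0, I1, I2)
    for i in range(3):
        if use_proxies:
            Fi = 1.0 - g[i]
            Di = g[i]
        else:
            Fi = y[12 + i]
            Di = y[15 + i]
        if i == 1:
            lat_u = 0.5 * (us[0] + us[2])
            sst_lat = b_fac * Fi * (ss[0] + ss[2])
        else:
            lat_u = us[1]
            sst_lat = b_fac * Fi * ss[1]
        J1 = -sst_lat + q * Is[i] + wee_l * lat_u
        J2 = q * Is[i] + wpe_l * lat_u
        J3 = wse_l * lat_u
        wep_eff = wep_t - a_dep * (1.0 - Di)
        du = (-us[i] + _f(
            wee * us[i] - wep_eff * ps[i] - wes_t * ss[i] + J1 - u_th, r
        )) / tau_u
        dp = (-ps[i] + _f(
            wpe * us[i] - wpp * ps[i] - wps * ss[i] + pv_val + J2 - p_th, r
        )) / tau_p
        ds = (-ss[i] + _f(
            wse * us[i] + sst_val + J3 - s_th_t, r
        )) / tau_s
        dy[i] = du
        dy[3 + i] = dp
        dy[6 + i] = ds
        dy[9 + i] = (g0 - g[i]) / tau_d1 - g[i] * iv[i] / tau_d2
        if use_proxies:
            dy[12 + i] = 0.0
            dy[15 + i] = 0.0
        else:
            dy[12 + i] = -y[12 + i] / tau_d1 + iv[i] / tau_d2
            dy[15 + i] = (1.0 - y[15 + i]) / tau_d1 - y[15 + i] * iv[i] / tau_d2
    ibar = iv[0] + iv[1] + iv[2]
    dy[18] = -Fbar * Fbar / tau_F1 + ibar / tau_F2
    return dy


@njit(cache=True)
def _run3(dt, n_steps, record_every,
          wee, wep, wes, wpe, wpp, wps, wse,
          u_th, p_th, s_th, r, tau_u, tau_p, tau_s,
          q, tau_q, tau_d1, tau_d2, g0,
          wee_l, wpe_l, wse_l, alpha, a_dep, b_fac,
          tau_F1, tau_F2, F_th, h_gain, smooth, use_proxies,
          tone_step, tone_unit, tone_amp,
          pv_win, pv_amp, sst_win, sst_amp,
          euler):
    y = np.zeros(19)
    y[9:12] = g0
    y[15:18] = 1.0
    iv = np.zeros(3)
    n_rec = n_steps // record_every + 1
    rec = np.zeros((n_rec, 23))
    dy1 = np.zeros(19)
    dy2 = np.zeros(19)
    dy3 = np.zeros(19)
    dy4 = np.zeros(19)
    yt = np.zeros(19)
    ivh = np.zeros(3)
    iv1 = np.zeros(3)
    kt = 0
    n_tones = tone_step.shape[0]
    pv_i = 0
    sst_i = 0
    rrow = 0
    dec_h = np.exp(-0.5 * dt / tau_q)
    dec_1 = dec_h * dec_h
    for step in range(n_steps + 1):
        t = step * dt
        while kt < n_tones and tone_step[kt] == step:
            iv[tone_unit[kt]] += tone_amp[kt]
            kt += 1
        if step % record_every == 0:
            rec[rrow, 0] = t
            rec[rrow, 1:20] = y
            rec[rrow, 20:23] = iv
            rrow += 1
        if step == n_steps:
            break
        pv0, pv_i = _opto_val(t, pv_win, pv_amp, pv_i)
        pvh, pv_j = _opto_val(t + 0.5 * dt, pv_win, pv_amp, pv_i)
        pv1, _ = _opto_val(t + dt * 0.999999, pv_win, pv_amp, pv_j)
        sst0, sst_i = _opto_val(t, sst_win, sst_amp, sst_i)
        ssth, sst_j = _opto_val(t + 0.5 * dt, sst_win, sst_amp, sst_i)
        sst1, _ = _opto_val(t + dt * 0.999999, sst_win, sst_amp, sst_j)
        for m in range(3):
            ivh[m] = iv[m] * dec_h
            iv1[m] = iv[m] * dec_1
        if euler:
            _rhs3(y, iv, pv0, sst0,
                  wee, wep, wes, wpe, wpp, wps, wse,
                  u_th, p_th, s_th, r, tau_u, tau_p, tau_s,
                  q, tau_d1, tau_d2, g0,
                  wee_l, wpe_l, wse_l, alpha, a_dep, b_fac,
                  tau_F1, tau_F2, F_th, h_gain, smooth, use_proxies, dy1)
            for m in range(19):
                y[m] += dt * dy1[m]
        else:
            _rhs3(y, iv, pv0, sst0,
                  wee, wep, wes, wpe, wpp, wps, wse,
                  u_th, p_th, s_th, r, tau_u, tau_p, tau_s,
                  q, tau_d1, tau_d2, g0,
                  wee_l, wpe_l, wse_l, alpha, a_dep, b_fac,
                  tau_F1, tau_F2, F_th, h_gain, smooth, use_proxies, dy1)
            for m in range(19):
                yt[m] = y[m] + 0.5 * dt * dy1[m]
            _rhs3(yt, ivh, pvh, ssth,
                  wee, wep, wes, wpe, wpp, wps, wse,
                  u_th, p_th, s_th, r, tau_u, tau_p, tau_s,
                  q, tau_d1, tau_d2, g0,
                  wee_l, wpe_l, wse_l, alpha, a_dep, b_fac,
                  tau_F1, tau_F2, F_th, h_gain, smooth, use_proxies, dy2)
            for m in range(19):
                yt[m] = y[m] + 0.5 * dt * dy2[m]
            _rhs3(yt, ivh, pvh, ssth,
                  wee, wep, wes, wpe, wpp, wps, wse,
                  u_th, p_th, s_th, r, tau_u, tau_p, tau_s,
                  q, tau_d1, tau_d2, g0,
                  wee_l, wpe_l, wse_l, alpha, a_dep, b_fac,
                  tau_F1, tau_F2, F_th, h_gain, smooth, use_proxies, dy3)
            for m in range(19):
                yt[m] = y[m] + dt * dy3[m]
            _rhs3(yt, iv1, pv1, sst1,
                  wee, wep, wes, wpe, wpp, wps, wse,
                  u_th, p_th, s_th, r, tau_u, tau_p, tau_s,
                  q, tau_d1, tau_d2, g0,
                  wee_l, wpe_l, wse_l, alpha, a_dep, b_fac,
                  tau_F1, tau_F2, F_th, h_gain, smooth, use_proxies, dy4)
            for m in range(19):
                y[m] += dt / 6.0 * (dy1[m] + 2.0 * dy2[m] + 2.0 * dy3[m] + dy4[m])
        for m in range(3):
            iv[m] = iv1[m]
        if not (np.isfinite(y[0]) and np.isfinite(y[3]) and np.isfinite(y[6])):
            raise ValueError("rate simulation produced a non-finite state")
    return rec


@njit(cache=True)
def _rhs1(y, ivv, pv_val, sst_val,
          wee, wep, wes, wpe, wpp, wps, wse, wsp, wss,
          u_th, p_th, s_th, r, tau_u, tau_p, tau_s,
          q, tau_d1, tau_d2, g0, dy):
    u, p, s, g = y[0], y[1], y[2], y[3]
    thal = q * g * ivv
    dy[0] = (-u + _f(wee * u - wep * p - wes * s + thal - u_th, r)) / tau_u
    dy[1] = (-p + _f(wpe * u - wpp * p - wps * s + pv_val + thal - p_th, r)) / tau_p
    dy[2] = (-s + _f(wse * u - wsp * p - wss * s + sst_val - s_th, r)) / tau_s
    dy[3] = (g0 - g) / tau_d1 - g * ivv / tau_d2
    return dy


@njit(cache=True)
def _run1(dt, n_steps, record_every,
          wee, wep, wes, wpe, wpp, wps, wse, wsp, wss,
          u_th, p_th, s_th, r, tau_u, tau_p, tau_s,
          q, tau_q, tau_d1, tau_d2, g0,
          tone_step, tone_amp,
          pv_win, pv_amp, sst_win, sst_amp,
          euler):
    y = np.zeros(4)
    y[3] = g0
    iv = 0.0
    n_rec = n_steps // record_every + 1
    rec = np.zeros((n_rec, 6))
    dy1 = np.zeros(4)
    dy2 = np.zeros(4)
    dy3 = np.zeros(4)
    dy4 = np.zeros(4)
    yt = np.zeros(4)
    kt = 0
    n_tones = tone_step.shape[0]
    pv_i = 0
    sst_i = 0
    rrow = 0
    dec_h = np.exp(-0.5 * dt / tau_q)
    dec_1 = dec_h * dec_h
    for step in range(n_steps + 1):
        t = step * dt
        while kt < n_tones and tone_step[kt] == step:
            iv += tone_amp[kt]
            kt += 1
        if step % record_every == 0:
            rec[rrow, 0] = t
            rec[rrow, 1:5] = y
            rec[rrow, 5] = iv
            rrow += 1
        if step == n_steps:
            break
        pv0, pv_i = _opto_val(t, pv_win, pv_amp, pv_i)
        pvh, pv_j = _opto_val(t + 0.5 * dt, pv_win, pv_amp, pv_i)
        pv1, _ = _opto_val(t + dt * 0.999999, pv_win, pv_amp, pv_j)
        sst0, sst_i = _opto_val(t, sst_win, sst_amp, sst_i)
        ssth, sst_j = _opto_val(t + 0.5 * dt, sst_win, sst_amp, sst_i)
        sst1, _ = _opto_val(t + dt * 0.999999, sst_win, sst_amp, sst_j)
        ivh = iv * dec_h
        iv1 = iv * dec_1
        if euler:
            _rhs1(y, iv, pv0, sst0, wee, wep, wes, wpe, wpp, wps, wse, wsp, wss,
                  u_th, p_th, s_th, r, tau_u, tau_p, tau_s,
                  q, tau_d1, tau_d2, g0, dy1)
            for m in range(4):
                y[m] += dt * dy1[m]
        else:
            _rhs1(y, iv, pv0, sst0, wee, wep, wes, wpe, wpp, wps, wse, wsp, wss,
                  u_th, p_th, s_th, r, tau_u, tau_p, tau_s,
                  q, tau_d1, tau_d2, g0, dy1)
            for m in range(4):
                yt[m] = y[m] + 0.5 * dt * dy1[m]
            _rhs1(yt, ivh, pvh, ssth, wee, wep, wes, wpe, wpp, wps, wse, wsp, wss,
                  u_th, p_th, s_th, r, tau_u, tau_p, tau_s,
                  q, tau_d1, tau_d2, g0, dy2)
            for m in range(4):
                yt[m] = y[m] + 0.5 * dt * dy2[m]
            _rhs1(yt, ivh, pvh, ssth, wee, wep, wes, wpe, wpp, wps, wse, wsp, wss,
                  u_th, p_th, s_th, r, tau_u, tau_p, tau_s,
                  q, tau_d1, tau_d2, g0, dy3)
            for m in range(4):
                yt[m] = y[m] + dt * dy3[m]
            _rhs1(yt, iv1, pv1, sst1, wee, wep, wes, wpe, wpp, wps, wse, wsp, wss,
                  u_th, p_th, s_th, r, tau_u, tau_p, tau_s,
                  q, tau_d1, tau_d2, g0, dy4)
            for m in range(4):
                y[m] += dt / 6.0 * (dy1[m] + 2.0 * dy2[m] + 2.0 * dy3[m] + dy4[m])
        iv = iv1
        if not np.isfinite(y[0]):
            raise ValueError("rate simulation produced a non-finite state")
    return rec


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

_EMPTY_WIN = np.zeros((0, 2))


def _merge_windows(windows: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent on-windows into disjoint sorted intervals."""
    if windows is None or len(windows) == 0:
        return _EMPTY_WIN
    w = windows[np.argsort(windows[:, 0])]
    merged = [list(w[0])]
    for on, off in w[1:]:
        if on <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], off)
        else:
            merged.append([on, off])
    return np.array(merged)


def _opto_arrays(opto, target: str) -> tuple[np.ndarray, float]:
    """Extract (windows, amplitude) for one target from opto schedule(s)."""
    scheds = []
    if opto is None:
        pass
    elif isinstance(opto, OptoSchedule):
        scheds = [opto]
    else:
        scheds = [o for o in opto if o is not None]
    for sched in scheds:
        if sched.target != target:
            continue
        if sched.mode == "sustained":
            return np.array([[-np.inf, np.inf]]), sched.amplitude
        return _merge_windows(sched.windows), sched.amplitude
    return _EMPTY_WIN, 0.0


def simulate_rate(
    params: RateParams | ThreeUnitRateParams,
    protocol: ToneProtocol,
    opto=None,
    dt: float = 0.1,
    n_units: int = 3,
    regime: str = "weak",
    record_every: int = 1,
    method: str = "rk4",
    smooth: bool = False,
) -> Trajectory:
    """Simulate the rate model and return a :class:`Trajectory`.

    ``regime`` is "weak", "strong" or "auto" (resolved once, before the
    run, from the Fbar asymptote of the protocol); it only applies to the
    three-unit model.  ``record_every`` subsamples the stored traces (state
    is still advanced at dt).  ``method`` is "rk4" (default) or "euler"
    (accuracy oracle).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if method not in ("rk4", "euler"):
        raise ValueError("method must be 'rk4' or 'euler'")
    euler = method == "euler"
    n_steps = int(round(protocol.span / dt))
    tone_step = np.array(
        [int(round(t.onset / dt)) for t in protocol.tones], dtype=np.int64
    )
    if np.any(tone_step > n_steps):
        raise ValueError("tone onset outside the simulation span")
    tone_unit = np.array([t.unit for t in protocol.tones], dtype=np.int64)
    tone_amp = np.array([t.amplitude for t in protocol.tones])
    pv_win, pv_amp = _opto_arrays(opto, "pv")
    sst_win, sst_amp = _opto_arrays(opto, "sst")

    if n_units == 1:
        if isinstance(params, ThreeUnitRateParams):
            base = params.base
        else:
            base = params
        W = base.W
        rec = _run1(
            dt, n_steps, record_every,
            W[0, 0], W[0, 1], W[0, 2], W[1, 0], W[1, 1], W[1, 2],
            W[2, 0], W[2, 1], W[2, 2],
            base.u_th, base.p_th, base.s_th, base.r,
            base.tau_u, base.tau_p, base.tau_s,
            base.q, base.tau_q, base.tau_d1, base.tau_d2, base.g0,
            tone_step, tone_amp, pv_win, pv_amp, sst_win, sst_amp,
            euler,
        )
        time = rec[:, 0]
        return Trajectory(
            time_ms=time,
            u=rec[:, 1:2].T, p=rec[:, 2:3].T, s=rec[:, 3:4].T,
            g=rec[:, 4:5].T, inputs=rec[:, 5:6].T,
            F=np.zeros((1, len(time))), D=np.ones((1, len(time))),
            Fbar=np.zeros(len(time)),
            params=params, regime="single", dt=dt,
            meta={
                "paradigm": protocol.paradigm, "n_units": 1,
                "method": method,
                "opto": {"pv": pv_amp, "sst": sst_amp},
            },
        )

    if n_units != 3:
        raise ValueError("n_units must be 1 or 3")
    if not isinstance(params, ThreeUnitRateParams):
        params = ThreeUnitRateParams(base=params)
    reg = regime_for(regime, protocol, params)
    W = reg.W
    base = params.base
    rec = _run3(
        dt, n_steps, record_every,
        W[0, 0], W[0, 1], W[0, 2], W[1, 0], W[1, 1], W[1, 2], W[2, 0],
        base.u_th, base.p_th, reg.s_th, base.r,
        base.tau_u, base.tau_p, base.tau_s,
        base.q, base.tau_q, base.tau_d1, base.tau_d2, base.g0,
        params.w_ee_lat, params.w_pe_lat, params.w_se_lat,
        params.alpha, params.a_dep, params.b_fac,
        params.tau_F1, params.tau_F2, params.F_th, params.h_gain,
        smooth, params.use_proxies,
        tone_step, tone_unit, tone_amp,
        pv_win, pv_amp, sst_win, sst_amp,
        euler,
    )
    time = rec[:, 0]
    g = rec[:, 10:13].T
    if params.use_proxies:
        F = 1.0 - g
        D = g.copy()
    else:
        F = rec[:, 13:16].T
        D = rec[:, 16:19].T
    return Trajectory(
        time_ms=time,
        u=rec[:, 1:4].T, p=rec[:, 4:7].T, s=rec[:, 7:10].T,
        g=g, F=F, D=D, Fbar=rec[:, 19],
        inputs=rec[:, 20:23].T,
        params=params, regime=reg.name, dt=dt,
        meta={
            "paradigm": protocol.paradigm, "n_units": 3,
            "method": method,
            "opto": {"pv": pv_amp, "sst": sst_amp},
        },
    )
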