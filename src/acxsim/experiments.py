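"""Figure-level experiment drivers.

Each ``run_*`` function wires a protocol, a model tier and the metrics into
one of the study's experiments:

* :func:`run_ssa` — oddball streams, per-post-deviant-tone Exc responses
  and the CSI from counterbalanced frequency blocks;
* :func:`run_csi_sweep` — CSI over a (circuit parameter x opto amplitude)
  grid with the low-rate / saturation validity mask;
* :func:`run_forward_suppression` — normalized probe responses versus
  masker frequency;
* :func:`run_tuning_adaptation` — tone-1 / tone-8 tuning curves and
  light-on/off ratios;
* :func:`run_feedforward_connectivity` — Pearson correlation between the
  Exc response and the thalamic input, control versus PV activation;
* :func:`run_balance_scan` — peak excitatory/inhibitory currents into Exc
  across input strengths and the fitted balance slope.

All drivers accept ``tier="rate"`` (deterministic) or ``tier="spiking"``
(seeded; results averaged over seeds by the caller).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import (
    BalanceResult,
    CorrelationResult,
    CSIResult,
    aligned_correlation,
    csi,
    ei_balance,
    tone_response,
    tuning_light_ratio,
)
from .params import PARADIGM_PRESETS, RateParams, SpikingParams, ThreeUnitRateParams
from .protocols import (
    make_forward_suppression,
    make_oddball,
    make_opto,
    make_single_tone,
    make_tuning_adaptation,
)
from .rate import simulate_rate
from .spiking import build_network, population_rate, simulate_spiking

__all__ = [
    "run_ssa",
    "SweepSpec",
    "run_csi_sweep",
    "run_forward_suppression",
    "run_tuning_adaptation",
    "run_feedforward_connectivity",
    "run_balance_scan",
]

CONDITIONS = ("control", "pv_suppress", "sst_suppress", "pv_activate", "sst_activate")


def _condition_opto(protocol, preset, condition, tier, amplitude=None):
    if condition == "control":
        return None
    target, mode = condition.split("_")
    mode = {"suppress": "suppress", "activate": "activate"}[mode]
    return make_opto(protocol, preset, target, mode, tier, amplitude=amplitude)


def _rate_center_trace(traj):
    return traj.time_ms, traj.u[1]


def _spiking_center_trace(result, smooth_ms=5.0):
    return population_rate(result, "exc", unit=1, bin_ms=1.0, smooth_ms=smooth_ms)


# ---------------------------------------------------------------------------
# SSA / oddball
# ---------------------------------------------------------------------------

@dataclass
class SSAReport:
    condition: str
    tier: str
    csi: CSIResult
    #: mean Exc response at post-deviant position 0 (deviant), 1, 2, ... 8
    position_mean: np.ndarray
    responses: dict  # block -> per-tone arrays (onset, unit, label, response)
    meta: dict = field(default_factory=dict)


def _tone_responses(time_ms, trace, protocol, measure="mean"):
    out = []
    for tone in protocol.tones:
        out.append(
            tone_response(time_ms, trace, tone.onset, tone.onset + tone.duration,
                          measure=measure)
        )
    return np.asarray(out)


def _post_deviant_positions(labels):
    """Position of each tone after the most recent deviant (deviant = 0)."""
    pos = np.full(len(labels), -1)
    last_dev = None
    for k, lab in enumerate(labels):
        if lab == "deviant":
            pos[k] = 0
            last_dev = k
        elif last_dev is not None:
            pos[k] = k - last_dev
    return pos


def run_ssa(
    tier: str = "rate",
    condition: str = "control",
    n_tones: int = 500,
    seed: int = 0,
    n_positions: int = 9,
    amplitude: float | None = None,
    params=None,
    min_standard: float = 0.1,
    network=None,
    sim_seed: int | None = None,
    measure: str = "peak",
) -> SSAReport:
    """Oddball experiment: CSI and per-post-deviant-position responses.

    Runs the two counterbalanced frequency blocks (standard/deviant roles
    swapped, identical timing).  The deviant response set pools all
    deviants; the standard set pools standards at positions >= 2 after a
    deviant.  The center-unit Exc response is the peak over each tone
    window (rate: dimensionless activity; spiking: Hz), matching the
    firing-rate floor used by the validity mask.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    q = PARADIGM_PRESETS["ssa"]["q"]
    responses = {}
    pools = {}  # unit -> {"dev": [...], "std": [...]}
    pos_acc = [[] for _ in range(n_positions)]
    for swap in (False, True):
        protocol = make_oddball(n_tones=n_tones, seed=seed, swap=swap)
        opto = _condition_opto(protocol, "ssa", condition, tier, amplitude)
        if tier == "rate":
            p = params or ThreeUnitRateParams()
            p = p.replace(base=p.base.replace(q=q))
            traj = simulate_rate(p, protocol, opto=opto,
                                 regime=PARADIGM_PRESETS["ssa"]["regime"],
                                 record_every=10)
            time_ms, trace = _rate_center_trace(traj)
        else:
            sp = params or SpikingParams()
            sp = SpikingParams(
                exc=sp.exc, pv=sp.pv, sst=sp.sst, synapses=sp.synapses,
                topology=sp.topology, q=q * 1000.0,
                tau_I=sp.tau_I, tau_D_fast=sp.tau_D_fast,
            )
            net = network or build_network(sp, seed=seed)
            res = simulate_spiking(
                net, protocol, sp, opto=opto,
                regime=PARADIGM_PRESETS["ssa"]["regime"],
                seed=(seed if sim_seed is None else sim_seed) + int(swap),
            )
            time_ms, trace = _spiking_center_trace(res)
        resp = _tone_responses(time_ms, trace, protocol, measure=measure)
        labels = [t.label for t in protocol.tones]
        units = np.array([t.unit for t in protocol.tones])
        pos = _post_deviant_positions(labels)
        responses["swap" if swap else "base"] = {
            "onset": np.array([t.onset for t in protocol.tones]),
            "unit": units,
            "label": labels,
            "response": resp,
            "position": pos,
        }
        dev_unit = 0 if swap else 2
        std_unit = 2 if swap else 0
        pools.setdefault(dev_unit, {"dev": [], "std": []})
        pools.setdefault(std_unit, {"dev": [], "std": []})
        is_dev = np.array([lab == "deviant" for lab in labels])
        pools[dev_unit]["dev"].extend(resp[is_dev])
        std_mask = (~is_dev) & (pos >= 2)
        pools[std_unit]["std"].extend(resp[std_mask])
        for k in range(n_positions):
            pos_acc[k].extend(resp[pos == k])
    d_f1 = float(np.mean(pools[0]["dev"]))
    d_f2 = float(np.mean(pools[2]["dev"]))
    s_f1 = float(np.mean(pools[0]["std"]))
    s_f2 = float(np.mean(pools[2]["std"]))
    saturated = max(s_f1, s_f2) >= 0.99 if tier == "rate" else False
    result = csi(d_f1, d_f2, s_f1, s_f2, min_standard=min_standard,
                 saturated=saturated)
    position_mean = np.array(
        [np.mean(v) if v else np.nan for v in pos_acc]
    )
    return SSAReport(
        condition=condition, tier=tier, csi=result,
        position_mean=position_mean, responses=responses,
        meta={"n_tones": n_tones, "seed": seed},
    )


# ---------------------------------------------------------------------------
# CSI parameter sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepSpec:
    """Grid of one circuit parameter against one opto amplitude axis."""

    param: str  # "w_ee" | "tau_d1"
    param_values: np.ndarray
    opto_target: str  # "pv" | "sst"
    opto_values: np.ndarray
    tier: str = "rate"
    n_tones: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        self.param_values = np.asarray(self.param_values, dtype=float)
        self.opto_values = np.asarray(self.opto_values, dtype=float)
        for v in (self.param_values, self.opto_values):
            if len(v) > 1 and not np.all(np.diff(v) > 0):
                raise ValueError("sweep grids must be strictly increasing")
        if self.param not in ("w_ee", "tau_d1"):
            raise ValueError("sweep parameter must be 'w_ee' or 'tau_d1'")
        if 0.0 not in self.opto_values:
            raise ValueError("the control point (opto amplitude 0) must be on the grid")


def _with_param(params: ThreeUnitRateParams, name: str, value: float):
    if name == "w_ee":
        W = params.base.W.copy()
        W[0, 0] = value
        return params.replace(base=params.base.replace(W=W))
    if name == "tau_d1":
        return params.replace(base=params.base.replace(tau_d1=value))
    raise ValueError(name)


def run_csi_sweep(spec: SweepSpec):
    """CSI over the sweep grid, with the validity mask.

    Returns a pandas DataFrame with columns (param, opto, csi, valid,
    d_f1, d_f2, s_f1, s_f2) in long format.
    """
    import pandas as pd

    rows = []
    for pv in spec.param_values:
        params = _with_param(ThreeUnitRateParams(), spec.param, pv)
        for ov in spec.opto_values:
            if ov == 0.0:
                condition = "control"
                amp = None
            else:
                condition = f"{spec.opto_target}_{'suppress' if ov < 0 else 'activate'}"
                amp = ov
            rep = run_ssa(
                tier=spec.tier, condition=condition, n_tones=spec.n_tones,
                seed=spec.seed, amplitude=amp, params=params,
            )
            rows.append({
                "param": pv, "opto": ov, "csi": rep.csi.csi,
                "valid": rep.csi.valid,
                "d_f1": rep.csi.d_f1, "d_f2": rep.csi.d_f2,
                "s_f1": rep.csi.s_f1, "s_f2": rep.csi.s_f2,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Forward suppression
# ---------------------------------------------------------------------------

def run_forward_suppression(
    tier: str = "rate",
    condition: str = "control",
    seed: int = 0,
    amplitude: float | None = None,
) -> dict:
    """Normalized probe response per masker frequency.

    Each masker frequency is an independent trial from rest (the masker
    varies between trials).  The probe (center unit) response is the peak
    Exc response in the probe window, normalized by the masker-absent
    probe response of the same condition.  Keys of the returned ``probe``
    dict are masker unit indices (0, 1, 2) plus ``None`` for the
    reference trial.
    """
    q = PARADIGM_PRESETS["fws"]["q"]
    probe = {}
    for masker in (0, 1, 2, None):
        protocol = make_forward_suppression(masker_unit=masker)
        opto = _condition_opto(protocol, "fws", condition, tier, amplitude)
        probe_tone = [t for t in protocol.tones
                      if t.label in ("probe", "probe_alone")][0]
        if tier == "rate":
            p = ThreeUnitRateParams()
            p = p.replace(base=p.base.replace(q=q))
            traj = simulate_rate(p, protocol, opto=opto,
                                 regime=PARADIGM_PRESETS["fws"]["regime"],
                                 record_every=10)
            time_ms, trace = _rate_center_trace(traj)
        else:
            sp = SpikingParams(q=q * 1000.0)
            net = build_network(sp, seed=seed)
            res = simulate_spiking(net, protocol, sp, opto=opto,
                                   regime=PARADIGM_PRESETS["fws"]["regime"],
                                   seed=seed)
            time_ms, trace = _spiking_center_trace(res)
        probe[masker] = tone_response(
            time_ms, trace, probe_tone.onset,
            probe_tone.onset + probe_tone.duration, measure="peak",
        )
    ref = probe.get(None)
    normalized = {
        k: (v / ref if ref and ref > 0 else np.nan)
        for k, v in probe.items() if k is not None
    }
    return {"condition": condition, "tier": tier, "probe": probe,
            "normalized": normalized, "reference": ref}


# ---------------------------------------------------------------------------
# Tuning-curve adaptation
# ---------------------------------------------------------------------------

def run_tuning_adaptation(
    tier: str = "rate",
    condition: str = "control",
    seed: int = 0,
    amplitude: float | None = None,
) -> dict:
    """Tone-1 and tone-8 center-unit tuning curves over frequency distance.

    A train of 8 tones is presented to each unit in turn; the center
    unit's peak Exc response to the first and last tone of each train is
    indexed by the distance between the stimulated unit and the center
    (0 = preferred frequency, 1 = sideband).  Light-on/off ratios against
    the control condition follow the same keys.
    """
    protocol = make_tuning_adaptation()
    opto = _condition_opto(protocol, "tca", condition, tier, amplitude)
    if tier == "rate":
        p = ThreeUnitRateParams()
        traj = simulate_rate(p, protocol, opto=opto, regime="strong", record_every=10)
        time_ms, trace = _rate_center_trace(traj)
    else:
        sp = SpikingParams()
        net = build_network(sp, seed=seed)
        res = simulate_spiking(net, protocol, sp, opto=opto, regime="strong", seed=seed)
        time_ms, trace = _spiking_center_trace(res)
    curves = {}  # (distance, tone index) -> response
    for tone in protocol.tones:
        k = int(tone.label.replace("tone", ""))
        if k in (1, 8):
            dist = abs(tone.unit - 1)
            curves[(dist, k)] = tone_response(
                time_ms, trace, tone.onset, tone.onset + tone.duration,
                measure="peak",
            )
    return {"condition": condition, "tier": tier, "curves": curves}


def tca_light_ratios(tier: str = "rate", condition: str = "pv_suppress",
                     seed: int = 0) -> dict:
    """Light-on/off response ratio table for a tuning-adaptation condition."""
    on = run_tuning_adaptation(tier, condition, seed=seed)["curves"]
    off = run_tuning_adaptation(tier, "control", seed=seed)["curves"]
    return tuning_light_ratio(on, off)


# ---------------------------------------------------------------------------
# Feedforward functional connectivity
# ---------------------------------------------------------------------------

def run_feedforward_connectivity(
    tier: str = "rate",
    seed: int = 0,
    window_ms: float = 300.0,
    align: str | None = None,
    amplitude: float | None = None,
) -> CorrelationResult:
    """Pearson correlation of the center Exc response with the thalamic input.

    The single-tone paradigm is run in the control condition and under
    sustained PV activation.  The correlation window spans tone onset to
    ``window_ms`` after onset.  For the rate tier both traces correlate
    as-is; for the spiking tier the PV-activated (delayed) trace is
    aligned to the reference by its cross-correlation peak.
    """
    protocol = make_single_tone(unit=1, n_trials=1)
    onset = protocol.tones[0].onset
    if align is None:
        align = "none" if tier == "rate" else "max_xcorr"
    traces = {}
    ref = None
    for condition in ("control", "pv_activate"):
        opto = _condition_opto(protocol, "pv_act", condition, tier, amplitude)
        if tier == "rate":
            p = ThreeUnitRateParams()
            traj = simulate_rate(p, protocol, opto=opto, regime="strong",
                                 record_every=10)
            time_ms, trace = _rate_center_trace(traj)
            if condition == "control":
                # thalamic input profile i(t): instantaneous rise with
                # exponential decay (the depression resource g is a separate
                # variable, not part of the plotted input)
                ref = traj.inputs[1].copy()
        else:
            sp = SpikingParams()
            net = build_network(sp, seed=seed)
            res = simulate_spiking(net, protocol, sp, opto=opto,
                                   regime="strong", seed=seed)
            time_ms, trace = _spiking_center_trace(res)
            if condition == "control":
                thal = res.thalamic[1]
                ref = np.interp(time_ms, res.sample_ms, thal)
        traces[condition] = (time_ms, trace)
    m = (traces["control"][0] >= onset) & (traces["control"][0] < onset + window_ms)
    ref_w = ref[m]
    ctrl_w = traces["control"][1][m]
    pert_w = traces["pv_activate"][1][m]
    r_c, _ = aligned_correlation(ctrl_w, ref_w, align="none")
    r_p, shift = aligned_correlation(pert_w, ref_w, align=align)
    dt = float(np.median(np.diff(traces["control"][0])))
    return CorrelationResult(
        r_control=r_c, r_perturbed=r_p, shift_ms=shift * dt,
        window_ms=(onset, onset + window_ms),
    )


# ---------------------------------------------------------------------------
# E/I balance
# ---------------------------------------------------------------------------

def run_balance_scan(
    tier: str = "rate",
    strengths=None,
    seed: int = 0,
    include_thalamic: bool | None = None,
) -> BalanceResult:
    """Excitatory vs inhibitory currents into Exc across input strengths.

    For each input strength ``q`` a single-tone run is performed; the
    recurrent excitatory and the inhibitory current into the Exc
    population are collected over all samples with suprathreshold Exc
    activity, and a line through the origin is fitted to the pooled
    (inhibitory, excitatory) scatter.  The thalamic drive is the varied
    *input* and is not part of the circuit currents unless
    ``include_thalamic``.

    The rate tier uses the single-unit circuit (recurrent w_ee u against
    w_ep p + w_es s); the spiking tier uses the mean synaptic currents
    into center-unit Exc neurons (ee against ep + es) over the response
    window.  By default the rate tier keeps the thalamic drive out of the
    excitatory current (it is the input being varied) while the spiking
    tier counts the thalamic current as excitatory drive alongside the
    recurrent one.
    """
    if include_thalamic is None:
        include_thalamic = tier == "spiking"
    if strengths is None:
        strengths = np.linspace(1.0, 8.0, 8) if tier == "rate" else \
            np.linspace(2000.0, 8000.0, 4)
    exc_pts, inh_pts = [], []
    for qv in strengths:
        if tier == "rate":
            base = RateParams(q=float(qv))
            protocol = make_single_tone(unit=0, n_trials=1)
            traj = simulate_rate(base, protocol, n_units=1, record_every=10)
            W = base.W
            exc = W[0, 0] * traj.u[0]
            if include_thalamic:
                exc = exc + base.q * traj.g[0] * traj.inputs[0]
            inh = W[0, 1] * traj.p[0] + W[0, 2] * traj.s[0]
            active = traj.u[0] > 0.0
            exc_pts.extend(exc[active])
            inh_pts.extend(inh[active])
        else:
            protocol = make_single_tone(unit=1, n_trials=1)
            sp = SpikingParams()
            net = build_network(sp, seed=seed)
            res = simulate_spiking(net, protocol, sp, regime="strong",
                                   seed=seed, q=float(qv))
            _, rate = _spiking_center_trace(res)
            if rate.max() <= 0:
                continue
            exc = res.currents["ee"].copy()
            if include_thalamic:
                exc = exc + res.currents["thal"]
            inh = -(res.currents["ep"] + res.currents["es"])
            tone = [t for t in protocol.tones][0]
            m = (res.sample_ms >= tone.onset) & \
                (res.sample_ms < tone.onset + tone.duration + 150.0)
            exc_pts.extend(np.abs(exc[m]))
            inh_pts.extend(np.abs(inh[m]))
    return ei_balance(exc_pts, inh_pts)
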