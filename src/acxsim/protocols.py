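"""Auditory protocols and optogenetic schedules for the four paradigms.

A :class:`ToneProtocol` is a sorted list of tones, each addressed to one of
the three iso-frequency units (0 = f1, 1 = f* center, 2 = f2).  The four
named paradigms are

``ssa``
    Oddball streams: 100 ms tones every 400 ms on the two edge units, one
    frequency standard (90 %), the other deviant (10 %); two
    counterbalanced blocks swap the roles.
``fws``
    Forward suppression: masker (50 ms) then probe (50 ms) to the center
    unit after a 20 ms gap; the masker frequency varies across trials, and
    a masker-absent control trial defines the unsuppressed reference.
``tca``
    Tuning-curve adaptation: trains of 8 tones (100 ms, 300 ms ISI) to each
    unit in turn, 2400 ms between trains.
``pv_act``
    A single 50 ms tone per 1 s trial, used with sustained PV activation.

Optogenetic drive is an additive current into PV and/or SST populations,
either tone-locked (on 100 ms before each tone onset, off 100 ms after the
tone offset) or sustained over the whole simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .params import PARADIGM_PRESETS, opto_amplitude

__all__ = [
    "Tone",
    "ToneProtocol",
    "OptoSchedule",
    "make_oddball",
    "make_forward_suppression",
    "make_tuning_adaptation",
    "make_single_tone",
    "make_opto",
]


@dataclass(frozen=True)
class Tone:
    onset: float  # ms
    duration: float  # ms
    unit: int  # target iso-frequency unit, 0..2
    amplitude: float = 1.0
    label: str = ""  # e.g. "standard" / "deviant" / "masker" / "probe"


@dataclass
class ToneProtocol:
    tones: list[Tone]
    span: float  # total simulated span, ms
    paradigm: str = ""
    trial_bounds: list[float] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.tones = sorted(self.tones, key=lambda t: t.onset)
        by_unit: dict[int, float] = {}
        for t in self.tones:
            if t.duration <= 0:
                raise ValueError("tone duration must be positive")
            if t.onset < 0 or t.onset + t.duration > self.span:
                raise ValueError("tone outside the simulation span")
            if t.unit in by_unit and t.onset < by_unit[t.unit]:
                raise ValueError("overlapping tones addressed to one unit")
            by_unit[t.unit] = t.onset + t.duration

    def tones_for_unit(self, unit: int) -> list[Tone]:
        return [t for t in self.tones if t.unit == unit]

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "paradigm": self.paradigm,
            "span": self.span,
            "seed": self.seed,
            "trial_bounds": list(self.trial_bounds),
            "tones": [
                [t.onset, t.duration, t.unit, t.amplitude, t.label]
                for t in self.tones
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ToneProtocol":
        return cls(
            tones=[Tone(*row[:4], label=row[4]) for row in d["tones"]],
            span=d["span"],
            paradigm=d.get("paradigm", ""),
            trial_bounds=list(d.get("trial_bounds", [])),
            seed=d.get("seed"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ToneProtocol":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class OptoSchedule:
    """Additive optogenetic current into PV and/or SST populations."""

    target: str  # "pv" | "sst"
    amplitude: float  # dimensionless (rate) or pA (spiking); sign = act/suppress
    mode: str = "tone_locked"  # or "sustained"
    windows: np.ndarray | None = None  # (n, 2) on/off times, tone_locked only
    pre_ms: float = 100.0
    post_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.target not in ("pv", "sst"):
            raise ValueError("opto target must be 'pv' or 'sst'")
        if self.mode not in ("tone_locked", "sustained"):
            raise ValueError("opto mode must be 'tone_locked' or 'sustained'")
        if self.mode == "tone_locked" and self.windows is None:
            raise ValueError("tone_locked schedule requires windows")
        if self.windows is not None:
            self.windows = np.atleast_2d(np.asarray(self.windows, dtype=float))

    def drive(self, t: float) -> float:
        """Opto current at time t (scalar; vectorized callers use windows)."""
        if self.mode == "sustained":
            return self.amplitude
        w = self.windows
        hit = (w[:, 0] <= t) & (t < w[:, 1])
        return self.amplitude if np.any(hit) else 0.0

    def trace(self, time_ms: np.ndarray) -> np.ndarray:
        """Opto current sampled on a time grid."""
        if self.mode == "sustained":
            return np.full_like(time_ms, self.amplitude, dtype=float)
        out = np.zeros_like(time_ms, dtype=float)
        for on, off in self.windows:
            out[(time_ms >= on) & (time_ms < off)] = self.amplitude
        return out


# ---------------------------------------------------------------------------
# Paradigm constructors
# ---------------------------------------------------------------------------

SSA_TONE_MS = 100.0
SSA_ISI_MS = 300.0
FWS_TONE_MS = 50.0
FWS_GAP_MS = 20.0
FWS_ITI_MS = 380.0
TCA_TONE_MS = 100.0
TCA_ISI_MS = 300.0
TCA_ITI_MS = 2400.0
PVACT_TONE_MS = 50.0
PVACT_ITI_MS = 950.0


def make_oddball(
    n_tones: int = 500,
    p_deviant: float = 0.1,
    units: tuple[int, int] = (0, 2),
    seed: int = 0,
    swap: bool = False,
    lead_in: float = 100.0,
) -> ToneProtocol:
    """Oddball stream on the two edge units.

    ``units`` is (standard, deviant); ``swap=True`` exchanges them for the
    counterbalanced block while keeping identical timing (the deviant
    placement depends only on the seed).  Deviants are never the first tone
    and never consecutive.
    """
    if not 0 < p_deviant < 1:
        raise ValueError("p_deviant must lie in (0, 1)")
    std_u, dev_u = (units[1], units[0]) if swap else units
    rng = np.random.default_rng(seed)
    is_dev = np.zeros(n_tones, dtype=bool)
    for k in range(1, n_tones):
        if not is_dev[k - 1]:
            is_dev[k] = rng.random() < p_deviant
    tones = []
    period = SSA_TONE_MS + SSA_ISI_MS
    for k in range(n_tones):
        tones.append(
            Tone(
                onset=lead_in + k * period,
                duration=SSA_TONE_MS,
                unit=dev_u if is_dev[k] else std_u,
                label="deviant" if is_dev[k] else "standard",
            )
        )
    span = lead_in + n_tones * period
    return ToneProtocol(tones, span=span, paradigm="ssa", seed=seed)


def make_forward_suppression(
    masker_unit: int | None = None,
    probe_unit: int = 1,
    lead_in: float = 100.0,
) -> ToneProtocol:
    """One masker/probe trial (or a masker-absent reference trial).

    The masker frequency varies *between* trials and each trial starts
    from rest, so a trial is one protocol: masker (50 ms) to
    ``masker_unit``, a 20 ms gap, then the probe (50 ms) to the center
    unit.  ``masker_unit=None`` gives the masker-absent reference trial
    that defines the unsuppressed probe response.
    """
    if probe_unit != 1:
        raise ValueError("the probe is fixed at the center unit")
    tones = []
    t = lead_in
    trial_len = FWS_TONE_MS + FWS_GAP_MS + FWS_TONE_MS + FWS_ITI_MS
    if masker_unit is not None:
        tones.append(Tone(t, FWS_TONE_MS, masker_unit, label="masker"))
    probe_on = t + FWS_TONE_MS + FWS_GAP_MS
    label = "probe" if masker_unit is not None else "probe_alone"
    tones.append(Tone(probe_on, FWS_TONE_MS, probe_unit, label=label))
    return ToneProtocol(tones, span=lead_in + trial_len, paradigm="fws",
                        trial_bounds=[0.0, lead_in + trial_len])


def make_tuning_adaptation(
    n_repeats: int = 8,
    units: tuple[int, ...] = (0, 1, 2),
    lead_in: float = 100.0,
) -> ToneProtocol:
    """Trains of ``n_repeats`` tones to each unit, 2400 ms between trains."""
    tones = []
    bounds = [0.0]
    t = lead_in
    for u in units:
        for k in range(n_repeats):
            tones.append(
                Tone(t + k * (TCA_TONE_MS + TCA_ISI_MS), TCA_TONE_MS, u,
                     label=f"tone{k + 1}")
            )
        t += (n_repeats - 1) * (TCA_TONE_MS + TCA_ISI_MS) + TCA_TONE_MS + TCA_ITI_MS
        bounds.append(t)
    return ToneProtocol(tones, span=t, paradigm="tca", trial_bounds=bounds)


def make_single_tone(
    unit: int = 1, n_trials: int = 1, tone_at: float = 100.0
) -> ToneProtocol:
    """One 50 ms tone per 1 s trial (the PV-activation stimulus)."""
    trial_len = PVACT_TONE_MS + PVACT_ITI_MS
    tones = [
        Tone(k * trial_len + tone_at, PVACT_TONE_MS, unit, label="tone")
        for k in range(n_trials)
    ]
    return ToneProtocol(
        tones,
        span=n_trials * trial_len,
        paradigm="pv_act",
        trial_bounds=[k * trial_len for k in range(n_trials + 1)],
    )


def make_opto(
    protocol: ToneProtocol,
    preset: str,
    target: str,
    condition: str = "suppress",
    tier: str = "rate",
    amplitude: float | None = None,
) -> OptoSchedule:
    """Optogenetic schedule for a paradigm preset.

    Tone-locked for ssa/fws, sustained for tca/pv_act.  The amplitude comes
    from the per-paradigm preset table unless overridden.  Tone-locked
    suppression windows open 100 ms before tone onset and close 100 ms
    after tone offset; tone-locked activation windows coincide with the
    tone (the laser is co-presented with the stimulus).
    """
    if preset not in PARADIGM_PRESETS:
        raise KeyError(f"unknown paradigm preset {preset!r}")
    if amplitude is None:
        amplitude = opto_amplitude(preset, target, condition, tier)
    mode = PARADIGM_PRESETS[preset]["opto_mode"]
    windows = None
    pre = post = 100.0 if condition == "suppress" else 0.0
    if mode == "tone_locked":
        windows = np.array(
            [[t.onset - pre, t.onset + t.duration + post] for t in protocol.tones]
        )
        windows[:, 0] = np.maximum(windows[:, 0], 0.0)
    return OptoSchedule(target=target, amplitude=amplitude, mode=mode,
                        windows=windows, pre_ms=pre, post_ms=post)
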