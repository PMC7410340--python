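"""Result containers: rate-model trajectories and spiking-network results."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "SpikeResult"]


@dataclass
class Trajectory:
    """Time-gridded traces of a rate-model run.

    Arrays ``u, p, s, g, F, D, inputs`` have shape (n_units, n_samples);
    ``Fbar`` has shape (n_samples,).  ``inputs`` holds the raw per-unit
    thalamic input traces i_k(t) (unit amplitude, before depression gating
    and cross-unit spread).
    """

    time_ms: np.ndarray
    u: np.ndarray
    p: np.ndarray
    s: np.ndarray
    g: np.ndarray
    F: np.ndarray
    D: np.ndarray
    Fbar: np.ndarray
    inputs: np.ndarray
    params: object
    regime: str
    dt: float
    meta: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return self.u.shape[0]

    def mixed_input(self, unit: int) -> np.ndarray:
        """Depression-gated thalamic input I_k(t) reaching ``unit``.

        For the three-unit model this includes the cross-unit spread
        (fraction alpha of the adjacent units' gated inputs); for a
        single-unit run it is g(t) i(t).
        """
        gi = self.g * self.inputs
        if self.n_units == 1:
            return gi[0]
        alpha = self.params.alpha
        if unit == 1:
            return alpha * (gi[0] + gi[2]) + gi[1]
        return gi[unit] + alpha * gi[1]

    def exc_drive_decomposition(self, unit: int = 1) -> tuple[np.ndarray, np.ndarray]:
        """Excitatory and inhibitory contributions to the Exc drive of ``unit``.

        Both are returned as nonnegative traces; the argument of the Exc
        gain function (before thresholding) equals ``exc - inh`` at every
        sample.
        """
        from .params import ThreeUnitRateParams, W_STRONG

        if self.n_units == 1:
            W = self.params.W if hasattr(self.params, "W") else self.params.base.W
            q = self.params.q if hasattr(self.params, "q") else self.params.base.q
            exc = W[0, 0] * self.u[0] + q * self.g[0] * self.inputs[0]
            inh = W[0, 1] * self.p[0] + W[0, 2] * self.s[0]
            return exc, inh
        p: ThreeUnitRateParams = self.params
        W = p.base.W.copy()
        if self.regime == "strong":
            W[0, 1] = W_STRONG[0, 1]
            W[0, 2] = W_STRONG[0, 2]
        q = p.base.q
        if unit == 1:
            lat_u = 0.5 * (self.u[0] + self.u[2])
            sst_lat = p.b_fac * self.F[1] * (self.s[0] + self.s[2])
        else:
            lat_u = self.u[1]
            sst_lat = p.b_fac * self.F[unit] * self.s[1]
        exc = W[0, 0] * self.u[unit] + q * self.mixed_input(unit) + p.w_ee_lat * lat_u
        wep_eff = W[0, 1] - p.a_dep * (1.0 - self.D[unit])
        inh = wep_eff * self.p[unit] + W[0, 2] * self.s[unit] + sst_lat
        return exc, inh

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format frame: (time_ms, unit, population, variable, value)."""
        rows = []
        named = {"u": self.u, "p": self.p, "s": self.s, "g": self.g,
                 "F": self.F, "D": self.D, "input": self.inputs}
        for var, arr in named.items():
            for k in range(self.n_units):
                rows.append(pd.DataFrame({
                    "time_ms": self.time_ms,
                    "unit": k,
                    "population": {"u": "exc", "p": "pv", "s": "sst"}.get(var, ""),
                    "variable": var,
                    "value": arr[k],
                }))
        rows.append(pd.DataFrame({
            "time_ms": self.time_ms, "unit": -1, "population": "",
            "variable": "Fbar", "value": self.Fbar,
        }))
        return pd.concat(rows, ignore_index=True)

    def save(self, directory: str | Path, stem: str = "trajectory") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / f"{stem}.csv", index=False)
        sidecar = {
            "regime": self.regime,
            "dt": self.dt,
            "meta": self.meta,
        }
        (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))


@dataclass
class SpikeResult:
    """Spiking-network output: event list plus sampled population traces.

    ``spike_times`` / ``spike_ids`` are parallel event arrays (ms, global
    neuron id).  ``sample_ms`` grids the recorded traces: ``thalamic`` is
    the per-unit thalamic current (pA) and ``currents`` holds mean synaptic
    current components into center-unit Exc neurons (pA), keyed by name
    ("ee", "thal", "ep", "es", "dend").
    """

    spike_times: np.ndarray
    spike_ids: np.ndarray
    n_neurons: int
    populations: dict  # name -> (start, stop) global-id ranges per unit
    sample_ms: np.ndarray
    thalamic: np.ndarray  # (n_units, n_samples), pA
    currents: dict[str, np.ndarray]
    dt: float
    seed: int
    span: float
    meta: dict = field(default_factory=dict)

    def spikes_of(self, pop: str, unit: int) -> tuple[np.ndarray, np.ndarray]:
        start, stop = self.populations[pop][unit]
        m = (self.spike_ids >= start) & (self.spike_ids < stop)
        return self.spike_times[m], self.spike_ids[m]

    def save(self, directory: str | Path, stem: str = "spikes") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(
            directory / f"{stem}_events.txt",
            np.column_stack([self.spike_times, self.spike_ids]),
            fmt=["%.3f", "%d"], header="time_ms neuron_id",
        )
        pops = {k: [list(map(int, rng)) for rng in v]
                for k, v in self.populations.items()}
        (directory / f"{stem}_populations.json").write_text(
            json.dumps({"populations": pops, "seed": self.seed,
                        "dt": self.dt, "meta": self.meta}, indent=1)
        )
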