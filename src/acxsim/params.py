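"""Parameter containers for the rate and spiking tiers of the microcircuit.

Conventions
-----------
Population order is always (e, p, s) = (excitatory, PV, SST).  Weight and
conductance matrices are indexed ``[postsynaptic][presynaptic]``, so
``W[0][1]`` is the PV -> Exc weight (w_ep).  Rate-model quantities are
dimensionless except time, which is in milliseconds.  Spiking quantities
use mV / ms / pA / nS / pF throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "W_WEAK",
    "W_STRONG",
    "GMAX_DEFAULT",
    "RateParams",
    "ThreeUnitRateParams",
    "SpikingPopulationParams",
    "SynapseParams",
    "TopologyParams",
    "SpikingParams",
    "PARADIGM_PRESETS",
    "opto_amplitude",
]

# Within-unit weight matrix under weak baseline inhibition (the default
# operating point): rows are postsynaptic (e, p, s), columns presynaptic.
W_WEAK = np.array(
    [
        [1.1, 2.0, 1.0],
        [1.0, 2.0, 2.0],
        [6.0, 0.0, 0.0],
    ]
)

# Strong baseline inhibition differs only in the inhibitory weights onto Exc.
W_STRONG = np.array(
    [
        [1.1, 3.0, 3.0],
        [1.0, 2.0, 2.0],
        [6.0, 0.0, 0.0],
    ]
)


def _weak_matrix() -> np.ndarray:
    return W_WEAK.copy()


@dataclass
class RateParams:
    """Parameters of a single iso-frequency Wilson-Cowan unit.

    The unit holds one excitatory population and PV / SST inhibitory
    subpopulations, with a threshold-linear gain, thalamic input with
    instantaneous rise / exponential decay, and slow thalamic synaptic
    depression g(t).
    """

    W: np.ndarray = field(default_factory=_weak_matrix)
    u_th: float = 0.7
    p_th: float = 1.0
    s_th: float = 1.0
    r: float = 3.0
    tau_u: float = 10.0  # ms
    tau_p: float = 10.0  # ms
    tau_s: float = 10.0  # ms
    q: float = 5.0  # thalamic input strength (dimensionless)
    tau_q: float = 10.0  # ms, input decay
    tau_d1: float = 1500.0  # ms, depression replenishment
    tau_d2: float = 20.0  # ms, depression depletion
    g0: float = 1.0

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (3, 3):
            raise ValueError("W must be 3x3 (rows postsynaptic e,p,s)")
        if np.any(self.W < 0):
            raise ValueError("W must be nonnegative entrywise")
        if self.W[2, 1] != 0 or self.W[2, 2] != 0:
            raise ValueError("SST receives no inhibition: W[2,1] = W[2,2] = 0")
        for name in ("tau_u", "tau_p", "tau_s", "tau_q", "tau_d1", "tau_d2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.r <= 0:
            raise ValueError("gain r must be positive")

    def replace(self, **kw) -> "RateParams":
        return replace(self, **kw)


@dataclass
class ThreeUnitRateParams:
    """Parameters of the three-unit tonotopic rate model.

    Adds lateral (between-unit) excitatory weights, thalamic cross-unit
    spread ``alpha``, short-term plasticity of the PV->Exc (depressing) and
    lateral SST->Exc (facilitating) synapses, and the slow baseline
    facilitation variable Fbar that selects the weak/strong inhibition
    regime against threshold ``F_th``.
    """

    base: RateParams = field(default_factory=RateParams)
    w_ee_lat: float = 0.667
    w_pe_lat: float = 1.25
    w_se_lat: float = 0.125
    alpha: float = 0.65  # thalamic cross-unit spread fraction
    a_dep: float = 0.5  # PV->Exc depression strength
    b_fac: float = 1.0  # lateral SST->Exc facilitation strength
    tau_F1: float = 1500.0  # ms, Fbar squared-decay constant
    tau_F2: float = 100.0  # ms, Fbar input constant
    F_th: float = 0.22  # regime threshold on the Fbar asymptote
    s_th_strong: float = 0.0
    h_gain: float = 25.0  # gain of the optional smooth regime switch
    use_proxies: bool = True  # F_i = 1 - g_i, D_i = g_i shortcuts

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        # Lateral weights are generally weaker than their within-unit
        # counterparts; the stated Exc->PV lateral weight (1.25) exceeds the
        # within-unit one (1), so only the Exc and SST rows are checked.
        W = self.base.W
        if not (self.w_ee_lat < W[0, 0] and self.w_se_lat < W[2, 0]):
            raise ValueError("lateral weights must be weaker than within-unit ones")
        # a_dep must keep (w_ep - a_dep*(1 - D)) positive for D in [0, 1]
        # in both regimes (w_ep >= 2 in both).
        if self.a_dep >= min(W_WEAK[0, 1], W_STRONG[0, 1]):
            raise ValueError("a_dep too large: w_ep - a_dep*(1-D) would change sign")

    def replace(self, **kw) -> "ThreeUnitRateParams":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Spiking tier
# ---------------------------------------------------------------------------

@dataclass
class SpikingPopulationParams:
    """AdEx parameters for one population (units: pF, mV, nS, pA, ms)."""

    C_m: float
    E_L: float
    g_L: float
    Delta_T: float
    V_T: float
    V_reset: float
    I_baseline: float  # pA
    g_sd: float = 0.0  # nS, soma<->dendrite coupling (Exc only)
    kappa: float = 0.3  # somatic-to-total surface ratio (Exc only)
    noise_sigma: float = 20.0  # mV, stationary free-membrane voltage std
    a_w: float = 4.0  # nS, subthreshold adaptation
    tau_w: float = 150.0  # ms
    b_w: float = 80.0  # pA, spike-triggered adaptation increment
    refractory: float = 2.0  # ms

    def __post_init__(self) -> None:
        if self.C_m <= 0 or self.Delta_T <= 0:
            raise ValueError("C_m and Delta_T must be positive")
        if not 0 < self.kappa < 1:
            raise ValueError("kappa must lie in (0, 1)")

    @property
    def spike_cutoff(self) -> float:
        """Numerical spike detection threshold, mV."""
        return self.V_T + 5.0 * self.Delta_T

    @property
    def tau_m(self) -> float:
        return self.C_m / self.g_L


def default_exc() -> SpikingPopulationParams:
    return SpikingPopulationParams(
        C_m=180.0, E_L=-60.0, g_L=6.25, Delta_T=1.0, V_T=-40.0,
        V_reset=-60.0, I_baseline=350.0, g_sd=18.75,
    )


def default_pv() -> SpikingPopulationParams:
    return SpikingPopulationParams(
        C_m=80.0, E_L=-60.0, g_L=5.0, Delta_T=0.25, V_T=-40.0,
        V_reset=-60.0, I_baseline=50.0,
    )


def default_sst() -> SpikingPopulationParams:
    return SpikingPopulationParams(
        C_m=80.0, E_L=-60.0, g_L=5.0, Delta_T=1.0, V_T=-45.0,
        V_reset=-60.0, I_baseline=25.0,
    )


# Peak synaptic conductances, nS, rows postsynaptic (e,p,s), cols presynaptic.
# The SST row carries only the Exc->SST conductance: SSTs receive no
# inhibition and no thalamic drive.
GMAX_DEFAULT = np.array(
    [
        [20.0, 40.0, 20.0],
        [240.0, 40.0, 12.0],
        [120.0, 0.0, 0.0],
    ]
)


def _gmax_default() -> np.ndarray:
    return GMAX_DEFAULT.copy()


def _tau_decay_default() -> np.ndarray:
    tau = np.ones((3, 3))
    tau[1, 0] = 25.0  # Exc -> PV
    tau[2, 0] = 15.0  # Exc -> SST
    return tau


@dataclass
class SynapseParams:
    """Conductance-synapse parameters of the spiking tier."""

    Gmax: np.ndarray = field(default_factory=_gmax_default)
    tau_decay: np.ndarray = field(default_factory=_tau_decay_default)  # ms
    E_exc: float = 0.0  # mV
    E_inh: float = -67.0  # mV
    a_pvE: float = 1.7  # PV->Exc depression scale
    tau_D1: float = 1000.0  # ms (PV->Exc depression, thalamic D_slow)
    tau_D2: float = 250.0  # ms
    b_fac: float = 3.0  # dendritic facilitation strength
    tau_F1: float = 1000.0  # ms
    tau_F2: float = 250.0  # ms
    # weak-regime overrides of the inhibitory conductances onto Exc
    g_ep_weak: float = 38.0  # nS
    g_es_weak: float = 19.0  # nS

    def __post_init__(self) -> None:
        self.Gmax = np.asarray(self.Gmax, dtype=float)
        self.tau_decay = np.asarray(self.tau_decay, dtype=float)
        if self.Gmax[2, 1] != 0 or self.Gmax[2, 2] != 0:
            raise ValueError("SST receives no inhibition: Gmax[2,1] = Gmax[2,2] = 0")
        if np.any(self.Gmax < 0) or np.any(self.tau_decay <= 0):
            raise ValueError("conductances must be >= 0 and decay constants > 0")

    def gmax_for_regime(self, regime: str) -> np.ndarray:
        G = self.Gmax.copy()
        if regime == "weak":
            G[0, 1] = self.g_ep_weak
            G[0, 2] = self.g_es_weak
        return G


@dataclass
class TopologyParams:
    """Sizes and connection probabilities of the three-unit spiking network."""

    n_exc: int = 1600
    n_pv: int = 200
    n_sst: int = 200
    n_units: int = 3
    p_ee: float = 0.1
    p_other: float = 0.6  # all other within-unit classes
    p_lateral: float = 0.1  # adjacent-unit, excitatory source only
    thalamic_spread: float = 0.85  # adjacent-unit thalamic amplitude factor

    def __post_init__(self) -> None:
        if min(self.n_exc, self.n_pv, self.n_sst) <= 0:
            raise ValueError("population sizes must be positive")
        for p in (self.p_ee, self.p_other, self.p_lateral):
            if not 0 <= p <= 1:
                raise ValueError("connection probabilities must lie in [0, 1]")


@dataclass
class SpikingParams:
    """Full parameter set of the spiking tier."""

    exc: SpikingPopulationParams = field(default_factory=default_exc)
    pv: SpikingPopulationParams = field(default_factory=default_pv)
    sst: SpikingPopulationParams = field(default_factory=default_sst)
    synapses: SynapseParams = field(default_factory=SynapseParams)
    topology: TopologyParams = field(default_factory=TopologyParams)
    q: float = 5000.0  # pA, thalamic drive scale (q = 5 on the nA scale)
    tau_I: float = 1.0  # ms, thalamic current rise
    tau_D_fast: float = 10.0  # ms, fast within-tone thalamic depression


# ---------------------------------------------------------------------------
# Paradigm presets (stimulus and optogenetic amplitudes per paradigm)
# ---------------------------------------------------------------------------

Tier = Literal["rate", "spiking"]

#: Per-paradigm defaults.  "q" is the rate-tier input strength (the spiking
#: tier reuses the same number on the pA scale, x1000); opto amplitudes are
#: (suppress, activate) per target.  Rate amplitudes are dimensionless;
#: spiking amplitudes are pA.  ``None`` marks values the source never states.
PARADIGM_PRESETS: dict[str, dict] = {
    "ssa": {
        "regime": "weak",
        "q": 5.0,
        "opto_mode": "tone_locked",
        "rate": {
            ("pv", "suppress"): -4.0,
            ("pv", "activate"): 0.5,
            ("sst", "suppress"): -2.0,
            ("sst", "activate"): 1.2,
        },
        "spiking": {
            ("pv", "suppress"): -200.0,
            ("sst", "suppress"): -1000.0,
        },
    },
    "fws": {
        "regime": "strong",
        "q": 1.3,
        "opto_mode": "tone_locked",
        "rate": {
            ("pv", "suppress"): -0.5,
            ("pv", "activate"): 0.25,
            ("sst", "suppress"): -0.5,
            ("sst", "activate"): 0.1,
        },
        "spiking": {
            ("pv", "suppress"): -200.0,
            ("pv", "activate"): 100.0,
            ("sst", "suppress"): -1000.0,
        },
    },
    "tca": {
        "regime": "strong",
        "q": 5.0,
        "opto_mode": "sustained",
        "rate": {
            ("pv", "suppress"): -0.5,
            ("pv", "activate"): 1.2,
            ("sst", "suppress"): -1.0,
            ("sst", "activate"): 0.1,
        },
        "spiking": {
            ("pv", "suppress"): -1000.0,
            ("sst", "suppress"): -1000.0,
        },
    },
    "pv_act": {
        "regime": "strong",
        "q": 5.0,
        "opto_mode": "sustained",
        "rate": {
            ("pv", "activate"): 2.0,
            ("pv", "suppress"): -2.0,
        },
        "spiking": {
            ("pv", "activate"): 500.0,
        },
    },
}


def opto_amplitude(preset: str, target: str, condition: str, tier: Tier) -> float:
    """Look up the optogenetic amplitude for (paradigm, target, condition, tier).

    Raises ``KeyError`` with a readable message for combinations the
    presets do not define.
    """
    try:
        table = PARADIGM_PRESETS[preset]
    except KeyError:
        raise KeyError(f"unknown paradigm preset {preset!r}") from None
    try:
        return table[tier][(target, condition)]
    except KeyError:
        raise KeyError(
            f"no {tier} opto amplitude defined for preset={preset!r}, "
            f"target={target!r}, condition={condition!r}"
        ) from None
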