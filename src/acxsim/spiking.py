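"""Conductance-based three-unit spiking network.

Each iso-frequency unit holds 1600 two-compartment (ball-and-stick)
adaptive-exponential integrate-and-fire excitatory neurons, 200 PV and
200 SST single-compartment AdEx interneurons.  Synapses are event-driven
conductances with exponential decay; the PV -> Exc synapse carries a slow
depression factor and the SST -> Exc synapse targets the dendrite, whose
coupling to the soma is scaled by a slow facilitation variable.  Thalamic
drive enters Exc and PV somas as q * I_fast * D_slow * D_fast built from
the tone square wave; adjacent units receive a 0.85-scaled copy.

Integration is Euler-Maruyama at dt = 0.05 ms with additive voltage noise
(stationary free-membrane std 20 mV); conductance decay is integrated
exactly between events.  The whole network update is a single numba
kernel; runs are bit-reproducible for a given (network seed, sim seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.ndimage import gaussian_filter1d

from .params import SpikingParams
from .protocols import OptoSchedule, ToneProtocol
from .results import SpikeResult

__all__ = [
    "NetworkRealization",
    "build_network",
    "thalamic_current",
    "adex_step",
    "dendrite_step",
    "simulate_spiking",
    "population_rate",
]


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------

@dataclass
class NetworkRealization:
    """Sampled connectivity of the three-unit network.

    Adjacency per synapse class is stored in CSC-like form: ``indptr`` over
    presynaptic local indices and a flat array of postsynaptic local
    indices.  Class names are target<-source pairs: ee, pe, se (Exc
    source), ep, pp (PV source), ps (SST source, PV target).
    """

    seed: int
    n_units: int
    sizes: dict  # pop -> per-unit size
    adjacency: dict  # class -> (indptr, targets)
    counts: dict = field(default_factory=dict)  # class -> realized synapse count

    def adjacency_hash(self) -> int:
        import zlib

        h = 0
        for name in sorted(self.adjacency):
            indptr, tgt = self.adjacency[name]
            h = zlib.crc32(tgt.tobytes(), zlib.crc32(indptr.tobytes(), h))
        return h


def _sample_block(rng, n_src, n_tgt, p, src_off, tgt_off, no_self=False):
    """Bernoulli adjacency for one (source unit, target unit) block."""
    if p <= 0:
        return (np.empty(0, np.int64), np.empty(0, np.int64))
    mask = rng.random((n_src, n_tgt)) < p
    if no_self:
        np.fill_diagonal(mask, False)
    src, tgt = np.nonzero(mask)
    return src + src_off, tgt + tgt_off


def build_network(params: SpikingParams, seed: int = 0) -> NetworkRealization:
    """Sample the connectivity of the three-unit spiking network.

    Within a unit, E->E pairs connect with probability 0.1 and every other
    class with 0.6; between adjacent units only excitatory-source classes
    connect, with probability 0.1.  Deterministic for a given seed.
    """
    top = params.topology
    rng = np.random.default_rng(seed)
    nU = top.n_units
    sizes = {"exc": top.n_exc, "pv": top.n_pv, "sst": top.n_sst}
    class_defs = {
        "ee": ("exc", "exc", top.p_ee, True),
        "pe": ("exc", "pv", top.p_other, False),
        "se": ("exc", "sst", top.p_other, False),
        "ep": ("pv", "exc", top.p_other, False),
        "pp": ("pv", "pv", top.p_other, True),
        "ps": ("sst", "pv", top.p_other, False),
        "es": ("sst", "exc", top.p_other, False),
    }
    adjacency = {}
    counts = {}
    for name, (src_pop, tgt_pop, p_within, no_self) in class_defs.items():
        n_src_u, n_tgt_u = sizes[src_pop], sizes[tgt_pop]
        srcs, tgts = [], []
        for su in range(nU):
            for tu in range(nU):
                if su == tu:
                    p = p_within
                elif abs(su - tu) == 1 and src_pop == "exc":
                    p = top.p_lateral
                else:
                    continue
                s, t = _sample_block(
                    rng, n_src_u, n_tgt_u, p,
                    su * n_src_u, tu * n_tgt_u,
                    no_self=no_self and su == tu,
                )
                srcs.append(s)
                tgts.append(t)
        src = np.concatenate(srcs) if srcs else np.empty(0, np.int64)
        tgt = np.concatenate(tgts) if tgts else np.empty(0, np.int64)
        order = np.argsort(src, kind="stable")
        src, tgt = src[order], tgt[order]
        indptr = np.zeros(nU * n_src_u + 1, dtype=np.int64)
        np.add.at(indptr, src + 1, 1)
        indptr = np.cumsum(indptr)
        adjacency[name] = (indptr, tgt.astype(np.int64))
        counts[name] = int(len(tgt))
    return NetworkRealization(
        seed=seed, n_units=nU, sizes=sizes, adjacency=adjacency, counts=counts
    )


# ---------------------------------------------------------------------------
# Single-step reference pieces (used directly by tests; the kernel inlines
# the same arithmetic)
# ---------------------------------------------------------------------------

def thalamic_current(state: tuple[float, float, float], sq: float, q: float) -> float:
    """Thalamic drive q * I_fast * D_slow * D_fast, pA.

    ``state`` is (I_fast, D_slow, D_fast); ``sq`` the 0/1 tone square wave.
    """
    i_fast, d_slow, d_fast = state
    return q * i_fast * d_slow * d_fast


def thalamic_state_rhs(
    state: tuple[float, float, float],
    sq: float,
    tau_I: float = 1.0,
    tau_D_fast: float = 10.0,
    tau_D1: float = 1000.0,
    tau_D2: float = 250.0,
) -> tuple[float, float, float]:
    """Derivatives of (I_fast, D_slow, D_fast) under the square wave drive."""
    i_fast, d_slow, d_fast = state
    return (
        (-i_fast + sq) / tau_I,
        (1.0 - d_slow) / tau_D1 - d_slow * sq / tau_D2,
        (1.0 - d_fast - sq) / tau_D_fast,
    )


def adex_step(V, w, I_total, pop, dt, noise=0.0):
    """One Euler-Maruyama AdEx update; returns (V, w, spiked).

    ``pop`` is a SpikingPopulationParams; ``I_total`` in pA, ``noise`` a
    standard-normal draw (scaled internally to the stationary 20 mV std).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    exp_arg = min((V - pop.V_T) / pop.Delta_T, (pop.spike_cutoff - pop.V_T) / pop.Delta_T)
    dV = (
        -pop.g_L * (V - pop.E_L)
        + pop.g_L * pop.Delta_T * np.exp(exp_arg)
        - w
        + I_total
    ) / pop.C_m
    noise_inc = pop.noise_sigma * np.sqrt(2.0 * dt / pop.tau_m)
    V_new = V + dt * dV + noise_inc * noise
    w_new = w + dt * (pop.a_w * (V - pop.E_L) - w) / pop.tau_w
    if not np.isfinite(V_new):
        raise FloatingPointError("non-finite membrane potential in adex_step")
    if V_new >= pop.spike_cutoff:
        return pop.V_reset, w_new + pop.b_w, True
    return V_new, w_new, False


def dendrite_step(V_D, V_soma, g_es, F, pop, syn, dt):
    """One Euler update of the dendritic compartment.

    Returns (V_D_new, I_dend) with the somatic coupling current
    I_dend = -g_sd (1 + b F)(V_soma - V_D)/(1 - kappa), pA.
    """
    dVD = (
        -pop.g_L * (V_D - pop.E_L)
        - pop.g_sd * (V_D - V_soma) / pop.kappa
        - g_es * (V_D - syn.E_inh)
    ) / pop.C_m
    I_dend = -pop.g_sd * (1.0 + syn.b_fac * F) * (V_soma - V_D) / (1.0 - pop.kappa)
    return V_D + dt * dVD, I_dend


# ---------------------------------------------------------------------------
# The network kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _run_network(
    dt, n_steps, seed,
    # population parameter vectors: [C_m, E_L, g_L, DT, V_T, V_reset,
    #   I_base, noise_inc, a_w, tau_w, b_w, refr_steps, cutoff]
    pe_, pp_, ps_,
    nE, nP, nS, nU,
    # synapse constants
    decay_ee, decay_ep, decay_es, decay_pe, decay_pp, decay_ps, decay_se,
    inc_ee, inc_ep, inc_es, inc_pe, inc_pp, inc_ps, inc_se,
    E_exc, E_inh, a_pvE, tau_D1, tau_D2, b_fac, tau_F1, tau_F2,
    g_sd, kappa,
    # adjacency (indptr, targets) per class
    ee_ptr, ee_tgt, pe_ptr, pe_tgt, se_ptr, se_tgt,
    ep_ptr, ep_tgt, pp_ptr, pp_tgt, ps_ptr, ps_tgt, es_ptr, es_tgt,
    # drive
    sq,  # (nU, n_steps) uint8 tone square wave per unit
    q, tau_I, tau_D_fast, spread,
    opto_pv, opto_sst,  # (n_steps,) pA
    # recording
    rec_every, max_spikes,
):
    np.random.seed(seed)
    nEt = nE * nU
    nPt = nP * nU
    nSt = nS * nU

    VE = np.full(nEt, pe_[1])
    VD = np.full(nEt, pe_[1])
    wE = np.zeros(nEt)
    refE = np.zeros(nEt, np.int64)
    gee = np.zeros(nEt)
    gep = np.zeros(nEt)
    ges = np.zeros(nEt)

    VP = np.full(nPt, pp_[1])
    wP = np.zeros(nPt)
    refP = np.zeros(nPt, np.int64)
    gpe = np.zeros(nPt)
    gpp = np.zeros(nPt)
    gps = np.zeros(nPt)

    VS = np.full(nSt, ps_[1])
    wS = np.zeros(nSt)
    refS = np.zeros(nSt, np.int64)
    gse = np.zeros(nSt)

    # per-unit slow variables
    i_fast = np.zeros(nU)
    d_slow = np.ones(nU)
    d_fast = np.ones(nU)
    F_dend = np.zeros(nU)
    D_pv = np.ones(nU)
    I_thal = np.zeros(nU)

    spike_t = np.zeros(max_spikes)
    spike_id = np.zeros(max_spikes, np.int64)
    n_spk = 0

    n_rec = n_steps // rec_every + 1
    rec_thal = np.zeros((nU, n_rec))
    # mean currents into center-unit Exc: ee, thal, ep, es(dend), dend-coupling
    rec_cur = np.zeros((5, n_rec))
    rrow = 0

    spiked_E = np.zeros(nEt, np.int64)
    spiked_P = np.zeros(nPt, np.int64)
    spiked_S = np.zeros(nSt, np.int64)

    c0 = nE  # center-unit Exc slice [c0, c0 + nE)

    for step in range(n_steps):
        t = step * dt
        # --- slow per-unit variables (Euler) and thalamic drive
        for u in range(nU):
            s_u = 1.0 if sq[u, step] > 0 else 0.0
            i_fast[u] += dt * (-i_fast[u] + s_u) / tau_I
            d_slow[u] += dt * ((1.0 - d_slow[u]) / tau_D1 - d_slow[u] * s_u / tau_D2)
            d_fast[u] += dt * (1.0 - d_fast[u] - s_u) / tau_D_fast
            F_dend[u] += dt * (-F_dend[u] / tau_F1 + s_u / tau_F2)
            D_pv[u] += dt * ((1.0 - D_pv[u]) / tau_D1 - D_pv[u] * s_u / tau_D2)
        for u in range(nU):
            prod = q * i_fast[u] * d_slow[u] * d_fast[u]
            I_thal[u] = prod
        # cross-unit spread (edge <-> center)
        t0 = I_thal[0]
        t1 = I_thal[1]
        t2 = I_thal[2]
        I_thal[0] = t0 + spread * t1
        I_thal[1] = t1 + spread * (t0 + t2)
        I_thal[2] = t2 + spread * t1

        # --- conductance decay (exact)
        for i in range(nEt):
            gee[i] *= decay_ee
            gep[i] *= decay_ep
            ges[i] *= decay_es
        for i in range(nPt):
            gpe[i] *= decay_pe
            gpp[i] *= decay_pp
            gps[i] *= decay_ps
        for i in range(nSt):
            gse[i] *= decay_se

        record = step % rec_every == 0
        if record:
            for u in range(nU):
                rec_thal[u, rrow] = I_thal[u]

        # --- Exc neurons
        nsp_E = 0
        sum_ee = 0.0
        sum_th = 0.0
        sum_ep = 0.0
        sum_es = 0.0
        sum_dd = 0.0
        for i in range(nEt):
            u = i // nE
            V = VE[i]
            I_ee = -gee[i] * (V - E_exc)
            I_ep = -gep[i] * (a_pvE * D_pv[u]) * (V - E_inh)
            I_es = -ges[i] * (VD[i] - E_inh)
            I_dd = -g_sd * (1.0 + b_fac * F_dend[u]) * (V - VD[i]) / (1.0 - kappa)
            # dendrite always integrates
            dVD = (
                -pe_[2] * (VD[i] - pe_[1])
                - g_sd * (VD[i] - V) / kappa
                + I_es
            ) / pe_[0]
            VD[i] += dt * dVD
            if record and c0 <= i < c0 + nE:
                sum_ee += I_ee
                sum_th += I_thal[u]
                sum_ep += I_ep
                sum_es += I_es
                sum_dd += I_dd
            wE[i] += dt * (pe_[8] * (V - pe_[1]) - wE[i]) / pe_[9]
            if refE[i] > 0:
                refE[i] -= 1
                continue
            exp_arg = (V - pe_[4]) / pe_[3]
            if exp_arg > 5.0:
                exp_arg = 5.0
            dV = (
                -pe_[2] * (V - pe_[1])
                + pe_[2] * pe_[3] * np.exp(exp_arg)
                - wE[i]
                + I_ee + I_ep + I_dd + pe_[6] + I_thal[u]
            ) / pe_[0]
            V += dt * dV + pe_[7] * np.random.normal()
            if V >= pe_[12]:
                VE[i] = pe_[5]
                wE[i] += pe_[10]
                refE[i] = np.int64(pe_[11])
                if n_spk < max_spikes:
                    spike_t[n_spk] = t
                    spike_id[n_spk] = i
                    n_spk += 1
                spiked_E[nsp_E] = i
                nsp_E += 1
            else:
                VE[i] = V
        if record:
            rec_cur[0, rrow] = sum_ee / nE
            rec_cur[1, rrow] = sum_th / nE
            rec_cur[2, rrow] = sum_ep / nE
            rec_cur[3, rrow] = sum_es / nE
            rec_cur[4, rrow] = sum_dd / nE

        # --- PV neurons
        nsp_P = 0
        for i in range(nPt):
            u = i // nP
            V = VP[i]
            wP[i] += dt * (pp_[8] * (V - pp_[1]) - wP[i]) / pp_[9]
            if refP[i] > 0:
                refP[i] -= 1
                continue
            I_syn = (
                -gpe[i] * (V - E_exc)
                - gpp[i] * (V - E_inh)
                - gps[i] * (V - E_inh)
            )
            exp_arg = (V - pp_[4]) / pp_[3]
            if exp_arg > 5.0:
                exp_arg = 5.0
            dV = (
                -pp_[2] * (V - pp_[1])
                + pp_[2] * pp_[3] * np.exp(exp_arg)
                - wP[i]
                + I_syn + pp_[6] + I_thal[u] + opto_pv[step]
            ) / pp_[0]
            V += dt * dV + pp_[7] * np.random.normal()
            if V >= pp_[12]:
                VP[i] = pp_[5]
                wP[i] += pp_[10]
                refP[i] = np.int64(pp_[11])
                if n_spk < max_spikes:
                    spike_t[n_spk] = t
                    spike_id[n_spk] = nEt + i
                    n_spk += 1
                spiked_P[nsp_P] = i
                nsp_P += 1
            else:
                VP[i] = V

        # --- SST neurons
        nsp_S = 0
        for i in range(nSt):
            V = VS[i]
            wS[i] += dt * (ps_[8] * (V - ps_[1]) - wS[i]) / ps_[9]
            if refS[i] > 0:
                refS[i] -= 1
                continue
            I_syn = -gse[i] * (V - E_exc)
            exp_arg = (V - ps_[4]) / ps_[3]
            if exp_arg > 5.0:
                exp_arg = 5.0
            dV = (
                -ps_[2] * (V - ps_[1])
                + ps_[2] * ps_[3] * np.exp(exp_arg)
                - wS[i]
                + I_syn + ps_[6] + opto_sst[step]
            ) / ps_[0]
            V += dt * dV + ps_[7] * np.random.normal()
            if V >= ps_[12]:
                VS[i] = ps_[5]
                wS[i] += ps_[10]
                refS[i] = np.int64(ps_[11])
                if n_spk < max_spikes:
                    spike_t[n_spk] = t
                    spike_id[n_spk] = nEt + nPt + i
                    n_spk += 1
                spiked_S[nsp_S] = i
                nsp_S += 1
            else:
                VS[i] = V

        # --- spike propagation
        for k in range(nsp_E):
            i = spiked_E[k]
            for j in range(ee_ptr[i], ee_ptr[i + 1]):
                gee[ee_tgt[j]] += inc_ee
            for j in range(pe_ptr[i], pe_ptr[i + 1]):
                gpe[pe_tgt[j]] += inc_pe
            for j in range(se_ptr[i], se_ptr[i + 1]):
                gse[se_tgt[j]] += inc_se
        for k in range(nsp_P):
            i = spiked_P[k]
            for j in range(ep_ptr[i], ep_ptr[i + 1]):
                gep[ep_tgt[j]] += inc_ep
            for j in range(pp_ptr[i], pp_ptr[i + 1]):
                gpp[pp_tgt[j]] += inc_pp
        for k in range(nsp_S):
            i = spiked_S[k]
            for j in range(ps_ptr[i], ps_ptr[i + 1]):
                gps[ps_tgt[j]] += inc_ps
            for j in range(es_ptr[i], es_ptr[i + 1]):
                ges[es_tgt[j]] += inc_es

        if record:
            rrow += 1

    return spike_t[:n_spk], spike_id[:n_spk], rec_thal, rec_cur


def _pop_vector(pop, dt):
    noise_inc = pop.noise_sigma * np.sqrt(2.0 * dt / pop.tau_m)
    return np.array([
        pop.C_m, pop.E_L, pop.g_L, pop.Delta_T, pop.V_T, pop.V_reset,
        pop.I_baseline, noise_inc, pop.a_w, pop.tau_w, pop.b_w,
        round(pop.refractory / dt), pop.spike_cutoff,
    ])


def simulate_spiking(
    network: NetworkRealization,
    protocol: ToneProtocol,
    params: SpikingParams | None = None,
    opto=None,
    dt: float = 0.05,
    seed: int = 0,
    regime: str = "strong",
    rec_dt: float = 1.0,
    q: float | None = None,
) -> SpikeResult:
    """Integrate the spiking network over a tone protocol.

    ``regime`` selects the inhibitory conductances onto Exc ("strong" is
    the printed matrix; "weak" lowers g_ep/g_es to 38/19 nS).  ``opto`` is
    an OptoSchedule or list of them (amplitudes in pA).  Reproducible for
    a given seed.
    """
    params = params or SpikingParams()
    top = params.topology
    syn = params.synapses
    nU = top.n_units
    nE, nP, nS = top.n_exc, top.n_pv, top.n_sst
    n_steps = int(round(protocol.span / dt))

    sq = np.zeros((nU, n_steps), dtype=np.uint8)
    for tone in protocol.tones:
        a = int(round(tone.onset / dt))
        b = int(round((tone.onset + tone.duration) / dt))
        sq[tone.unit, a:b] = 1

    time_steps = np.arange(n_steps) * dt
    opto_pv = np.zeros(n_steps)
    opto_sst = np.zeros(n_steps)
    scheds = [opto] if isinstance(opto, OptoSchedule) else list(opto or [])
    for sched in scheds:
        if sched is None:
            continue
        tr = sched.trace(time_steps)
        if sched.target == "pv":
            opto_pv += tr
        else:
            opto_sst += tr

    G = syn.gmax_for_regime(regime)
    tau = syn.tau_decay
    decay = np.exp(-dt / tau)
    q_val = params.q if q is None else q

    rec_every = max(1, int(round(rec_dt / dt)))
    span_s = protocol.span / 1000.0
    max_spikes = int((nE + nP + nS) * nU * span_s * 150) + 100_000

    adj = network.adjacency
    spike_t, spike_id, rec_thal, rec_cur = _run_network(
        dt, n_steps, seed,
        _pop_vector(params.exc, dt), _pop_vector(params.pv, dt),
        _pop_vector(params.sst, dt),
        nE, nP, nS, nU,
        decay[0, 0], decay[0, 1], decay[0, 2],
        decay[1, 0], decay[1, 1], decay[1, 2], decay[2, 0],
        G[0, 0] / nE, G[0, 1] / nP, G[0, 2] / nS,
        G[1, 0] / nE, G[1, 1] / nP, G[1, 2] / nS, G[2, 0] / nE,
        syn.E_exc, syn.E_inh, syn.a_pvE, syn.tau_D1, syn.tau_D2,
        syn.b_fac, syn.tau_F1, syn.tau_F2,
        params.exc.g_sd, params.exc.kappa,
        *adj["ee"], *adj["pe"], *adj["se"],
        *adj["ep"], *adj["pp"], *adj["ps"], *adj["es"],
        sq, q_val, params.tau_I, params.tau_D_fast, top.thalamic_spread,
        opto_pv, opto_sst,
        rec_every, max_spikes,
    )
    if len(spike_t) >= max_spikes:
        raise RuntimeError("spike buffer overflow: pathological firing rates")

    nEt, nPt = nE * nU, nP * nU
    populations = {
        "exc": [(u * nE, (u + 1) * nE) for u in range(nU)],
        "pv": [(nEt + u * nP, nEt + (u + 1) * nP) for u in range(nU)],
        "sst": [(nEt + nPt + u * nS, nEt + nPt + (u + 1) * nS) for u in range(nU)],
    }
    sample_ms = np.arange(rec_thal.shape[1]) * rec_every * dt
    return SpikeResult(
        spike_times=spike_t,
        spike_ids=spike_id,
        n_neurons=(nE + nP + nS) * nU,
        populations=populations,
        sample_ms=sample_ms,
        thalamic=rec_thal,
        currents={
            "ee": rec_cur[0], "thal": rec_cur[1], "ep": rec_cur[2],
            "es": rec_cur[3], "dend": rec_cur[4],
        },
        dt=dt,
        seed=seed,
        span=protocol.span,
        meta={"paradigm": protocol.paradigm, "regime": regime,
              "q": q_val, "network_seed": network.seed},
    )


def population_rate(
    result: SpikeResult,
    pop: str,
    unit: int = 1,
    bin_ms: float = 1.0,
    smooth_ms: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed per-neuron population rate trace in Hz.

    Spike counts per ``bin_ms`` bin are normalized by (bin width x
    population size) and Gaussian-smoothed with std ``smooth_ms``.
    Returns (bin centers ms, rate Hz).
    """
    if bin_ms <= 0:
        raise ValueError("bin width must be positive")
    start, stop = result.populations[pop][unit]
    n = stop - start
    if n <= 0:
        raise ValueError("empty population")
    times, _ = result.spikes_of(pop, unit)
    n_bins = int(np.ceil(result.span / bin_ms))
    counts, edges = np.histogram(times, bins=n_bins, range=(0.0, n_bins * bin_ms))
    rate = counts / (n * bin_ms / 1000.0)
    if smooth_ms > 0:
        rate = gaussian_filter1d(rate, smooth_ms / bin_ms)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, rate
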