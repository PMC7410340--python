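"""Spiking tier: connectivity, AdEx pieces, network integration contracts."""

import numpy as np
import pytest

from acxsim.params import SpikingParams, TopologyParams
from acxsim.protocols import Tone, ToneProtocol, make_single_tone
from acxsim.spiking import (
    adex_step,
    build_network,
    dendrite_step,
    population_rate,
    simulate_spiking,
    thalamic_current,
    thalamic_state_rhs,
)


class TestBuildNetwork:
    def test_zero_probability_gives_no_synapses(self):
        params = SpikingParams(topology=TopologyParams(
            n_exc=50, n_pv=10, n_sst=10, p_ee=0.0, p_other=0.0, p_lateral=0.0
        ))
        net = build_network(params, seed=0)
        assert all(c == 0 for c in net.counts.values())

    def test_within_unit_counts_near_binomial_mean(self, small_spiking_params):
        net = build_network(small_spiking_params, seed=42)
        top = small_spiking_params.topology
        # E->PV: per unit n_exc*n_pv ordered pairs at p=0.6, plus lateral
        # blocks at p=0.1 (4 adjacent ordered unit pairs)
        mean = 3 * top.n_exc * top.n_pv * 0.6 + 4 * top.n_exc * top.n_pv * 0.1
        sd = np.sqrt(mean)  # upper bound on the binomial sd
        assert abs(net.counts["pe"] - mean) < 4 * sd

    def test_no_self_connections(self, small_spiking_params):
        net = build_network(small_spiking_params, seed=7)
        indptr, tgt = net.adjacency["ee"]
        for i in range(len(indptr) - 1):
            assert i not in tgt[indptr[i]:indptr[i + 1]]

    def test_seed_determinism(self, small_spiking_params):
        a = build_network(small_spiking_params, seed=5)
        b = build_network(small_spiking_params, seed=5)
        c = build_network(small_spiking_params, seed=6)
        assert a.adjacency_hash() == b.adjacency_hash()
        assert a.adjacency_hash() != c.adjacency_hash()

    def test_lateral_connections_are_excitatory_source_only(
        self, small_spiking_params
    ):
        net = build_network(small_spiking_params, seed=1)
        top = small_spiking_params.topology
        # PV -> Exc adjacency must stay within the source unit
        indptr, tgt = net.adjacency["ep"]
        for i in range(len(indptr) - 1):
            unit = i // top.n_pv
            t = tgt[indptr[i]:indptr[i + 1]]
            assert np.all(t // top.n_exc == unit)


class TestThalamicCurrent:
    def test_equilibrium_without_tone(self):
        assert thalamic_current((0.0, 1.0, 1.0), 0.0, 5000.0) == 0.0
        d = thalamic_state_rhs((0.0, 1.0, 1.0), 0.0)
        assert d == (0.0, 0.0, 0.0)

    def test_fast_depression_steady_state_is_zero_during_tone(self):
        # with the square wave on, dD_fast/dt = (1 - D_fast - 1)/tau = 0
        # at D_fast = 0
        d = thalamic_state_rhs((1.0, 1.0, 0.0), 1.0)
        assert d[2] == pytest.approx(0.0)

    def test_current_scales_with_q(self):
        s = (0.5, 0.8, 0.6)
        assert thalamic_current(s, 1.0, 2000.0) == pytest.approx(
            2 * thalamic_current(s, 1.0, 1000.0)
        )


class TestAdexStep:
    def test_rest_is_nearly_stationary_without_noise(self):
        sp = SpikingParams()
        V, w, spiked = adex_step(-60.0, 0.0, 0.0, sp.exc, dt=0.05)
        assert not spiked
        # exponential term at 20 mV below V_T is negligible
        assert abs(V - (-60.0)) < 1e-6

    def test_fI_monotonicity(self):
        sp = SpikingParams()

        def rate(I):
            V, w, n = sp.exc.E_L, 0.0, 0
            for _ in range(20000):  # 1 s at dt=0.05
                V, w, spiked = adex_step(V, w, I, sp.exc, dt=0.05)
                n += spiked
            return n

        r1, r2 = rate(300.0), rate(600.0)
        assert 0 < r1 < r2

    def test_adaptation_fixed_point_under_clamped_voltage(self):
        sp = SpikingParams()
        V = -50.0
        w = 0.0
        for _ in range(100000):
            _, w, _ = adex_step(V, w, 0.0, sp.exc, dt=0.05)
            # re-clamp V by discarding the voltage update
        assert w == pytest.approx(sp.exc.a_w * (V - sp.exc.E_L), rel=1e-3)

    def test_nonpositive_dt_rejected(self):
        sp = SpikingParams()
        with pytest.raises(ValueError):
            adex_step(-60.0, 0.0, 0.0, sp.exc, dt=0.0)


class TestDendriteStep:
    def test_no_coupling_at_equal_potentials(self):
        sp = SpikingParams()
        _, I = dendrite_step(-60.0, -60.0, 0.0, 0.0, sp.exc, sp.synapses, 0.05)
        assert I == 0.0

    def test_facilitation_scales_coupling_fourfold(self):
        sp = SpikingParams()
        _, I0 = dendrite_step(-55.0, -60.0, 0.0, 0.0, sp.exc, sp.synapses, 0.05)
        _, I1 = dendrite_step(-55.0, -60.0, 0.0, 1.0, sp.exc, sp.synapses, 0.05)
        assert I1 == pytest.approx((1 + sp.synapses.b_fac) * I0)

    def test_sst_conductance_hyperpolarizes_dendrite(self):
        sp = SpikingParams()
        V1, _ = dendrite_step(-60.0, -60.0, 0.0, 0.0, sp.exc, sp.synapses, 0.5)
        V2, _ = dendrite_step(-60.0, -60.0, 50.0, 0.0, sp.exc, sp.synapses, 0.5)
        assert V2 < V1


class TestSimulateSpiking:
    def _quiet_params(self):
        from acxsim.params import (
            SpikingParams, TopologyParams, default_exc, default_pv, default_sst
        )
        exc = default_exc()
        pv = default_pv()
        sst = default_sst()
        for pop in (exc, pv, sst):
            pop.I_baseline = 0.0
            pop.noise_sigma = 0.0
        return SpikingParams(
            exc=exc, pv=pv, sst=sst,
            topology=TopologyParams(n_exc=40, n_pv=10, n_sst=10),
        )

    def test_silent_without_drive_or_noise(self):
        params = self._quiet_params()
        net = build_network(params, seed=0)
        prot = ToneProtocol([], span=200.0)
        res = simulate_spiking(net, prot, params, seed=0)
        assert len(res.spike_times) == 0

    def test_seed_determinism(self, small_spiking_params):
        net = build_network(small_spiking_params, seed=3)
        prot = make_single_tone(unit=1, n_trials=1)
        a = simulate_spiking(net, prot, small_spiking_params, seed=11)
        b = simulate_spiking(net, prot, small_spiking_params, seed=11)
        assert np.array_equal(a.spike_times, b.spike_times)
        assert np.array_equal(a.spike_ids, b.spike_ids)
        c = simulate_spiking(net, prot, small_spiking_params, seed=12)
        assert not (
            len(a.spike_times) == len(c.spike_times)
            and np.array_equal(a.spike_times, c.spike_times)
        )

    def test_refractory_invariant(self, small_spiking_params):
        net = build_network(small_spiking_params, seed=3)
        prot = make_single_tone(unit=1, n_trials=1)
        res = simulate_spiking(net, prot, small_spiking_params, seed=4)
        refr = small_spiking_params.exc.refractory
        order = np.lexsort((res.spike_times, res.spike_ids))
        ids = res.spike_ids[order]
        times = res.spike_times[order]
        same = ids[1:] == ids[:-1]
        gaps = times[1:] - times[:-1]
        assert np.all(gaps[same] >= refr - 1e-9)

    def test_baseline_drive_increases_exc_rate(self, small_spiking_params):
        import dataclasses
        net = build_network(small_spiking_params, seed=3)
        prot = ToneProtocol([], span=500.0)
        res_lo = simulate_spiking(net, prot, small_spiking_params, seed=5)
        boosted = dataclasses.replace(small_spiking_params.exc, I_baseline=700.0)
        hi_params = dataclasses.replace(small_spiking_params, exc=boosted)
        res_hi = simulate_spiking(net, prot, hi_params, seed=5)

        def exc_count(res):
            return sum(
                len(res.spikes_of("exc", u)[0]) for u in range(3)
            )

        assert exc_count(res_hi) > exc_count(res_lo)

    def test_tone_evokes_pv_before_sst(self, small_spiking_params):
        # PVs receive direct thalamic drive; SSTs only disynaptically via
        # Exc, so the PV response rises first.  The half-rise latency is
        # the robust readout (the absolute peak time is confounded by the
        # refractory-limited saturation of the PV rate).
        net = build_network(small_spiking_params, seed=0)
        prot = make_single_tone(unit=1, n_trials=1)
        res = simulate_spiking(net, prot, small_spiking_params, seed=2)

        def half_rise(pop):
            t, r = population_rate(res, pop, 1, smooth_ms=3.0)
            base = r[(t > 20.0) & (t < 95.0)].mean()
            win = (t >= 100.0) & (t <= 250.0)
            peak = r[win].max()
            idx = np.nonzero(win & (r >= base + 0.5 * (peak - base)))[0]
            return t[idx[0]]

        assert half_rise("pv") < half_rise("sst")


class TestPopulationRate:
    def test_zero_and_counting_identity(self, small_spiking_params):
        net = build_network(small_spiking_params, seed=3)
        prot = make_single_tone(unit=1, n_trials=1)
        res = simulate_spiking(net, prot, small_spiking_params, seed=9)
        t, r = population_rate(res, "exc", 1, bin_ms=1.0, smooth_ms=0.0)
        n = small_spiking_params.topology.n_exc
        total = r.sum() * n * 1.0 / 1000.0  # rate*N*binwidth = count
        assert total == pytest.approx(len(res.spikes_of("exc", 1)[0]))

    def test_empty_population_rejected(self, small_spiking_params):
        net = build_network(small_spiking_params, seed=3)
        prot = ToneProtocol([], span=100.0)
        res = simulate_spiking(net, prot, small_spiking_params, seed=0)
        res.populations["ghost"] = [(0, 0)]
        with pytest.raises(ValueError):
            population_rate(res, "ghost", 0)

    def test_bad_bin_width_rejected(self, small_spiking_params):
        net = build_network(small_spiking_params, seed=3)
        prot = ToneProtocol([], span=100.0)
        res = simulate_spiking(net, prot, small_spiking_params, seed=0)
        with pytest.raises(ValueError):
            population_rate(res, "exc", 0, bin_ms=0.0)
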