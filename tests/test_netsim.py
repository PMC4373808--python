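"""Network construction and event-driven LIF simulation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import kinising as ki
from kinising.netsim import (ConfigurationError, circular_distance,
                             draw_poisson_train, euler_reference,
                             mean_spatial_connection_prob, sample_delays,
                             simulate_given_external, spatial_connection_prob,
                             std_steady_state)


# ---------------------------------------------------------------------------
# topology

class TestRandomNetwork:
    def test_connection_density_binomial(self):
        net = ki.make_random_network(50, 0.3, ki.EfficacySpec.delta(0.9),
                                     ki.DelaySpec.constant(3.0), seed=0)
        n_pairs = 50 * 49
        frac = (net.j_true != 0).sum() / n_pairs
        # 4 sigma binomial band around 0.30
        assert abs(frac - 0.30) < 4 * np.sqrt(0.3 * 0.7 / n_pairs)

    def test_empty_and_full(self):
        empty = ki.make_random_network(10, 0.0, ki.EfficacySpec.delta(0.9),
                                       ki.DelaySpec.constant(3.0), seed=0)
        assert not empty.j_true.any()
        full = ki.make_random_network(10, 1.0, ki.EfficacySpec.delta(0.9),
                                      ki.DelaySpec.constant(3.0), seed=0)
        off = ~np.eye(10, dtype=bool)
        assert np.all(full.j_true[off] == 0.9)
        assert np.all(np.diag(full.j_true) == 0)

    def test_sign_constant_per_presynaptic_population(self):
        net = ki.make_random_network(40, 0.4, ki.EfficacySpec.delta(0.54),
                                     ki.DelaySpec.constant(3.0),
                                     population_split=0.5, seed=3)
        for j in range(40):
            col = net.j_true[:, j]
            nz = col[col != 0]
            assert np.all(np.sign(nz) == net.labels[j])

    def test_delays_positive_where_connected(self):
        net = ki.make_random_network(30, 0.2, ki.EfficacySpec.delta(0.9),
                                     ki.DelaySpec.truncated_exponential(1, 20), seed=4)
        assert np.all(net.delays[net.j_true != 0] > 0)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigurationError):
            ki.make_random_network(10, 1.5, ki.EfficacySpec.delta(0.9),
                                   ki.DelaySpec.constant(3.0))
        with pytest.raises(ConfigurationError):
            ki.EfficacySpec.uniform(1.0, 0.5)
        with pytest.raises(ConfigurationError):
            ki.DelaySpec.truncated_exponential(5.0, 2.0)

    def test_topology_independent_of_delay_spec(self):
        """Named seed substreams: changing the delay spec keeps the topology."""
        a = ki.make_random_network(30, 0.2, ki.EfficacySpec.delta(0.9),
                                   ki.DelaySpec.constant(3.0), seed=7)
        b = ki.make_random_network(30, 0.2, ki.EfficacySpec.delta(0.9),
                                   ki.DelaySpec.truncated_exponential(1, 20), seed=7)
        assert np.array_equal(a.j_true != 0, b.j_true != 0)


class TestRingNetwork:
    @pytest.mark.parametrize("a,b,p,expect", [(7, 7, 100, 0), (1, 100, 100, 1),
                                              (10, 60, 100, 50), (3, 98, 100, 5)])
    def test_circular_distance(self, a, b, p, expect):
        assert circular_distance(a, b, p) == expect

    @given(st.integers(1, 60), st.integers(1, 60))
    def test_circular_distance_symmetric_and_bounded(self, a, b):
        d = circular_distance(a, b, 60)
        assert d == circular_distance(b, a, 60)
        assert 0 <= d <= 30

    def test_kernel_center_and_mean(self):
        assert spatial_connection_prob(50, 50, 100) == pytest.approx(0.134)
        assert mean_spatial_connection_prob(100) == pytest.approx(0.050, abs=0.002)

    def test_kernel_plugin_value(self):
        # direct evaluation of the two exponential factors
        expect = 0.134 * np.exp(-circular_distance(60, 62, 100) / 135.0
                                - circular_distance(60, 50, 100) / 26.1)
        assert spatial_connection_prob(60, 62, 100) == pytest.approx(expect)

    def test_ring_connection_fraction_and_efficacies(self):
        net = ki.make_ring_network(1000, 100, ki.EfficacySpec.gaussian(0.846, 0.211),
                                   ki.DelaySpec.truncated_exponential(1, 15), seed=8)
        n_pairs = 1000 * 999
        frac = (net.j_true != 0).sum() / n_pairs
        assert frac == pytest.approx(0.050, abs=0.004)
        vals = net.j_true[net.j_true != 0]
        assert vals.mean() == pytest.approx(0.846, abs=3 * 0.211 / np.sqrt(len(vals)))

    def test_flat_kernel_reduces_to_erdos_renyi(self):
        net = ki.make_ring_network(200, 200, ki.EfficacySpec.gaussian(0.8, 0.1),
                                   ki.DelaySpec.constant(3.0), seed=9,
                                   pair_scale=1e12, ref_scale=1e12)
        frac = (net.j_true != 0).sum() / (200 * 199)
        assert frac == pytest.approx(0.134, abs=4 * np.sqrt(0.134 * 0.866 / (200 * 199)))

    def test_p_must_divide_n(self):
        with pytest.raises(ConfigurationError):
            ki.make_ring_network(10, 3, ki.EfficacySpec.gaussian(0.8, 0.1),
                                 ki.DelaySpec.constant(3.0))


class TestDelaySampling:
    def test_constant(self, rng):
        out = sample_delays(ki.DelaySpec.constant(3.0), 10, rng)
        assert np.all(out == 3.0)

    def test_truncated_range_and_scale_rule(self, rng):
        spec = ki.DelaySpec.truncated_exponential(1.0, 20.0)
        assert spec.effective_scale == pytest.approx(19.0 / np.log(20.0))
        out = sample_delays(spec, 50_000, rng)
        assert out.min() >= 1.0 and out.max() <= 20.0

    def test_resample_fraction_five_percent(self, rng):
        spec = ki.DelaySpec.truncated_exponential(1.0, 20.0)
        n = 1_000_000
        _, n_rej = sample_delays(spec, n, rng, count_resamples=True)
        # fraction of pre-truncation draws that exceeded the cutoff
        frac = n_rej / (n + n_rej)
        assert frac == pytest.approx(0.05, abs=0.002)


# ---------------------------------------------------------------------------
# simulation

class TestSimulate:
    def test_silent_without_input(self):
        net = ki.make_random_network(5, 0.5, ki.EfficacySpec.delta(0.9),
                                     ki.DelaySpec.constant(3.0), seed=0,
                                     external=ki.ExternalDriveSpec(nu_ext=0.0))
        rec = ki.simulate(net, 1000.0, seed=1)
        assert rec.total_spikes == 0

    def test_seed_determinism(self):
        net = ki.make_random_network(20, 0.3, ki.EfficacySpec.delta(0.9),
                                     ki.DelaySpec.constant(3.0), seed=5)
        a = ki.simulate(net, 5000.0, seed=42)
        b = ki.simulate(net, 5000.0, seed=42)
        c = ki.simulate(net, 5000.0, seed=43)
        for ta, tb in zip(a.trains, b.trains):
            assert np.array_equal(ta, tb)
        assert any(not np.array_equal(ta, tc) for ta, tc in zip(a.trains, c.trains))

    def test_refractoriness(self, fig1_record, fig1_net):
        tau_ref = fig1_net.neuron.tau_refractory
        for train in fig1_record.trains:
            if len(train) > 1:
                assert np.diff(train).min() >= tau_ref - 1e-12

    def test_spike_times_within_duration(self, fig1_record):
        for train in fig1_record.trains:
            assert np.all((train >= 0) & (train < fig1_record.duration))

    def test_subthreshold_mean_potential(self, rng):
        """Shot-noise drive below threshold: mean V = V_rest + tau_m J nu."""
        neuron = ki.NeuronParams(theta=-20.0)  # threshold far away: no spikes
        net = ki.NetworkModel(j_true=np.zeros((1, 1)), delays=np.zeros((1, 1)),
                              neuron=neuron,
                              external=ki.ExternalDriveSpec(nu_ext=0.5, j_ext_mean=0.9))
        ext = [draw_poisson_train(0.5, 100_000.0, rng)]
        rec, vtr = euler_reference(net, ext, 100_000.0, dt_step=0.01)
        assert rec.total_spikes == 0
        # discard transient, then compare to -70 + 20 * 0.9 * 0.5 = -61 mV
        assert vtr[0, 20_000:].mean() == pytest.approx(-61.0, abs=0.5)

    def test_event_driven_matches_euler_reference(self, rng):
        """Same external realization into both integrators: same rates."""
        j = np.array([[0.0, 0.0, 0.0],
                      [0.9, 0.0, 0.0],
                      [0.9, 0.9, 0.0]])
        d = np.where(j != 0, 3.0, 0.0)
        net = ki.NetworkModel(j_true=j, delays=d)
        dur = 50_000.0
        ext = [draw_poisson_train(1.0, dur, rng) for _ in range(3)]
        rec_ev = simulate_given_external(net, ext, dur)
        rec_eu, _ = euler_reference(net, ext, dur, dt_step=0.01)
        for i in range(3):
            n_ev, n_eu = len(rec_ev.trains[i]), len(rec_eu.trains[i])
            # Euler at 0.01 ms carries O(dt_step) discretization error; allow
            # a few percent on top of Poisson counting error
            assert abs(n_ev - n_eu) < 0.05 * max(n_ev, 1) + 4 * np.sqrt(max(n_ev, 1))

    def test_fig1_population_rate(self, fig1_record):
        """Self-exciting 50-neuron benchmark fires in the tens of Hz."""
        assert 40.0 < fig1_record.mean_rate_hz() < 70.0


class TestSTD:
    def test_steady_state_closed_form(self):
        assert std_steady_state(0.0, 800.0, 0.1) == 1.0
        assert std_steady_state(0.2, 800.0, 0.00625) == pytest.approx(0.5)

    def test_per_spike_map_fixed_point_matches_steady_state(self):
        """Iterating the per-arrival update over Poisson arrivals reproduces
        the 1/(1+u*tau_r*nu) time-averaged resource within 5%."""
        u, tau_r, nu = 0.2, 800.0, 0.00625
        rng = np.random.default_rng(0)
        gaps = rng.exponential(1.0 / nu, size=int(nu * 500_000) + 1000)
        r, t_int, r_int = 1.0, 0.0, 0.0
        for g in gaps:
            # time-average of r(t) = 1 - (1-r) exp(-t/tau_r) over the gap
            r_int += g - (1 - r) * tau_r * (1 - np.exp(-g / tau_r))
            t_int += g
            r = 1 - (1 - r) * np.exp(-g / tau_r)
            r = r * (1 - u)
        assert r_int / t_int == pytest.approx(std_steady_state(u, tau_r, nu), rel=0.05)

    def test_periodic_fixed_point_matches_simulated_map(self):
        """Closed-form fixed point of the periodic-input map r ->
        (1-u)(1 - (1-r)exp(-1/(nu tau_r))) vs long-run iteration."""
        u, tau_r, nu = 0.2, 800.0, 0.01
        q = np.exp(-1.0 / (nu * tau_r))
        fixed = (1 - u) * (1 - q) / (1 - (1 - u) * q)
        r = 1.0
        for _ in range(500):
            r = (1 - u) * (1 - (1 - r) * q)
        assert r == pytest.approx(fixed, rel=1e-9)
        assert 0.0 <= fixed <= 1.0

    def test_engine_depression_deterministic_arrivals(self):
        """Drive the pre-synaptic neuron with scheduled suprathreshold
        impulses; the engine's depressed synapse must make the post neuron
        fire exactly on the arrivals predicted by the resource map."""
        u, tau_r = 0.5, 200.0
        period = 50.0
        j = np.zeros((2, 2))
        j[1, 0] = 19.0          # suprathreshold only at r close to 1
        d = np.zeros((2, 2))
        d[1, 0] = 1.0
        net = ki.NetworkModel(j_true=j, delays=d,
                              std=ki.STDParams(enabled=True, tau_r=tau_r, u=u))
        dur = 5000.0
        drive = np.arange(1.0, dur - 10, period)   # pre spikes at these times
        rec = simulate_given_external(net, [drive + 0.0, np.empty(0)], dur,
                                      ext_amps=[np.full(len(drive), 30.0), np.empty(0)])
        assert np.allclose(rec.trains[0], drive)
        # replay the resource map: post fires when 19 * r(t-) >= 18
        r, t_last, expected = 1.0, None, []
        for t in drive + 1.0:   # arrival times at the post neuron
            if t_last is not None:
                r = 1 - (1 - r) * np.exp(-(t - t_last) / tau_r)
            if 19.0 * r >= 18.0:
                expected.append(t)
            r *= (1 - u)
            t_last = t
        assert np.allclose(rec.trains[1], np.array(expected))
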