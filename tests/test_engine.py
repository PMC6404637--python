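"""Integration engine: single-neuron physics, STP fixed points, determinism,
noise calibration, discretization robustness."""

import math

import numpy as np
import pytest

from pfcwm import NetworkSpec, StimulusProtocol, build_layout, run, sample_connectivity


def v_trace(result, neuron, tau):
    """Membrane potential per step recovered from the leak channel
    (leak increment = -(dt/tau) V, recorded at bin_ms = dt)."""
    return -result.leak[:, neuron] * tau / result.dt


def make_single(mu_E, sigma_E):
    spec = NetworkSpec(
        N_E=1, N_I=1, p=1, f=1.0, c=0.0, mu_ext=(mu_E, 0.0), sigma_ext=(sigma_E, 0.0)
    )
    return spec, sample_connectivity(spec, build_layout(spec), seed=0)


class TestSingleNeuron:
    def test_free_decay_is_exponential(self):
        """No input: V relaxes as V0 * exp(-t/tau) (Euler-discretized)."""
        spec, tab = make_single(0.0, 0.0)
        res = run(spec, tab, (1, 1), [], 50.0, 0.1, seed=1, bin_ms=0.1)
        assert res.spike_t.size == 0
        v = v_trace(res, 0, 15.0)
        # discrete map: V_{n+1} = (1 - dt/tau) V_n
        ratio = v[1:] / v[:-1]
        np.testing.assert_allclose(ratio, 1 - 0.1 / 15.0, rtol=1e-9)
        # and the discrete solution tracks the continuous exponential to O(dt)
        t = res.dt * np.arange(v.size)
        np.testing.assert_allclose(v, v[0] * np.exp(-t / 15.0), rtol=2e-2)

    def test_suprathreshold_period_matches_closed_form(self):
        """Constant drive mu > theta: ISI = tau_arp + tau ln((mu-V_r)/(mu-theta))."""
        spec, tab = make_single(23.8, 0.0)
        res = run(spec, tab, (1, 1), [], 2000.0, 0.1, seed=1, record_currents=False)
        isis = np.diff(res.spike_t[res.spike_i == 0])
        expected = 2.0 + 15.0 * math.log((23.8 - 16.0) / (23.8 - 20.0))
        assert isis.mean() == pytest.approx(expected, rel=0.02)
        # deterministic drive: the period is a constant on the dt grid
        assert np.ptp(isis) <= res.dt + 1e-9

    def test_discrete_period_matches_scalar_recursion_oracle(self):
        """The engine's spike times equal an independently coded scalar
        forward-Euler recursion, step for step."""
        spec, tab = make_single(23.8, 0.0)
        res = run(spec, tab, (1, 1), [], 500.0, 0.1, seed=1, bin_ms=0.1)
        dt, tau, mu = 0.1, 15.0, 23.8
        # the leak channel records -(dt/tau) V *before* the update, so the
        # first recorded value is exactly the engine's initial condition
        v, ref, spikes = v_trace(res, 0, tau)[0], 0, []
        for n in range(5000):
            if ref > 0:
                ref -= 1
                v = 16.0
                continue
            v += (dt / tau) * (mu - v)
            if v >= 20.0:
                spikes.append(n * dt)
                v = 16.0
                ref = 20
        np.testing.assert_allclose(res.spike_t, spikes, atol=1e-9)

    def test_free_membrane_noise_statistics(self):
        """With synapses absent, the stationary membrane mean is mu_ext and
        its SD is sigma_ext (the dt-invariant noise discretization)."""
        spec, tab = make_single(10.0, 1.0)
        res = run(spec, tab, (1, 1), [], 20000.0, 0.1, seed=2, bin_ms=0.1)
        v = v_trace(res, 0, 15.0)[2000:]  # discard transient
        # ~600 effective samples (T / 2 tau): 3 SE on the mean is ~0.12
        assert v.mean() == pytest.approx(10.0, abs=0.12)
        assert v.std() == pytest.approx(1.0, abs=0.05)

    def test_refractory_period_enforced(self):
        spec, tab = make_single(30.0, 2.0)
        res = run(spec, tab, (1, 1), [], 3000.0, 0.1, seed=3, record_currents=False)
        isis = np.diff(res.spike_t[res.spike_i == 0])
        assert isis.min() >= spec.tau_arp


class TestSTP:
    def test_event_driven_fixed_point_at_10hz(self):
        """Periodic ~10 Hz firing: time-averaged u and x match the exact
        event-driven recursion (and u its mean-field value loosely)."""
        ratio = math.exp(98.0 / 15.0)  # drive tuned for a 100 ms period
        mu = (16.0 - 20.0 * ratio) / (1.0 - ratio)
        spec, tab = make_single(mu, 0.0)
        res = run(spec, tab, (1, 1), [], 20000.0, 0.1, seed=1, bin_ms=5.0)
        isis = np.diff(res.spike_t[res.spike_i == 0])
        T = isis.mean()
        U, X, tau_u, tau_x = 0.2, 1.0, 1500.0, 200.0
        # steady-state jump/decay recursion (independent closed form)
        E_u, E_x = math.exp(-T / tau_u), math.exp(-T / tau_x)
        u_pre = U / (1 - (1 - U) * E_u)
        u_post = u_pre + U * (1 - u_pre)
        x_pre = (X * (1 - E_x)) / (1 - (1 - u_post) * E_x)
        x_post = x_pre * (1 - u_post)
        u_bar = U + (u_post - U) * (tau_u / T) * (1 - E_u)
        x_bar = X + (x_post - X) * (tau_x / T) * (1 - E_x)
        skip = res.u_trace.shape[0] // 4
        assert res.u_trace[skip:, 0].mean() == pytest.approx(u_bar, rel=0.02)
        assert res.x_trace[skip:, 0].mean() == pytest.approx(x_bar, rel=0.03)
        # mean-field facilitation fixed point u* = U(1+r tau_u)/(1+U r tau_u) = 0.8
        r = 1.0 / T
        u_star = U * (1 + r * tau_u) / (1 + U * r * tau_u)
        assert u_star == pytest.approx(0.8, abs=0.01)
        assert res.u_trace[skip:, 0].mean() == pytest.approx(u_star, rel=0.10)

    def test_state_bounds_under_network_activity(self, tiny_spec, tiny_table):
        res = run(tiny_spec, tiny_table, (1.3, 1.0), [], 500.0, 0.1, seed=4, bin_ms=1.0)
        assert np.all(res.u_trace >= 0) and np.all(res.u_trace <= 1 + 1e-12)
        assert np.all(res.x_trace >= 0) and np.all(res.x_trace <= tiny_spec.X + 1e-12)
        assert res.spike_t.size > 0  # the check is vacuous on a silent net


class TestNetworkRuns:
    def test_determinism_under_fixed_seed(self, tiny_spec, tiny_table):
        a = run(tiny_spec, tiny_table, (1, 1), [], 300.0, 0.1, seed=7, record_currents=False)
        b = run(tiny_spec, tiny_table, (1, 1), [], 300.0, 0.1, seed=7, record_currents=False)
        assert np.array_equal(a.spike_t, b.spike_t)
        assert np.array_equal(a.spike_i, b.spike_i)
        c = run(tiny_spec, tiny_table, (1, 1), [], 300.0, 0.1, seed=8, record_currents=False)
        assert not (c.spike_t.size == a.spike_t.size and np.array_equal(a.spike_t, c.spike_t))

    def test_seed_required(self, tiny_spec, tiny_table):
        with pytest.raises(ValueError, match="seed"):
            run(tiny_spec, tiny_table, (1, 1), [], 100.0, 0.1)

    def test_spike_times_on_grid_and_refractory(self, tiny_spec, tiny_table):
        res = run(tiny_spec, tiny_table, (1, 1), [], 400.0, 0.1, seed=9, record_currents=False)
        frac = res.spike_t / res.dt
        np.testing.assert_allclose(frac, np.round(frac), atol=1e-6)
        for i in np.unique(res.spike_i)[:50]:
            t = np.sort(res.spike_t[res.spike_i == i])
            if t.size > 1:
                assert np.diff(t).min() >= tiny_spec.tau_arp

    def test_stimulus_raises_target_rate(self, tiny_spec, tiny_layout, tiny_table):
        stim = [StimulusProtocol("Es1", 100.0, 200.0, A_cue=1.15)]
        res = run(tiny_spec, tiny_table, (1, 1), stim, 400.0, 0.1, seed=10, record_currents=False)
        r_stim = res.population_rate(tiny_layout, "Es1", 100.0, 300.0)
        r_other = res.population_rate(tiny_layout, "Es2", 100.0, 300.0)
        assert r_stim > 2 * max(r_other, 0.5)

    def test_dt_halving_changes_rates_under_5_percent(self):
        """Discretization robustness in a mean-driven reference config."""
        spec = NetworkSpec(N_E=200, N_I=50, p=2, f=0.2, c=0.3)
        tab = sample_connectivity(spec, build_layout(spec), seed=11)
        lay = build_layout(spec)
        r = {}
        for dt in (0.1, 0.05):
            res = run(spec, tab, (1, 1), [], 1000.0, dt, seed=12, record_currents=False)
            lo, hi = 0, spec.N_E
            t, _ = res.spikes_in(lo, hi, 200.0)
            r[dt] = t.size
        assert abs(r[0.1] - r[0.05]) / max(r[0.05], 1) < 0.05

    def test_current_channels_account_for_membrane_update(self, tiny_spec, tiny_table):
        """Between resets, the four recorded channels sum to the potential
        change over each sampling bin (conservation of the decomposition)."""
        spec, tab = make_single(15.0, 0.5)
        res = run(spec, tab, (1, 1), [], 1000.0, 0.1, seed=13, bin_ms=0.1)
        assert res.spike_t.size == 0
        v = v_trace(res, 0, 15.0)
        # v_trace[n] is V before step n, so the step-n increments take it to v_trace[n+1]
        total = (res.rec_e + res.rec_i + res.ext + res.leak)[:, 0]
        np.testing.assert_allclose(np.diff(v), total[:-1], atol=1e-9)
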