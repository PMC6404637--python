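"""Phase classification, persistence rule, bisection search, state metrics."""

import math

import numpy as np
import pytest

from pfcwm import NetworkSpec, SimResult, build_layout
from pfcwm.protocols import (
    NOT_LOADABLE,
    PersistenceCriterion,
    _bisect_duration,
    check_persistence,
    classify_phase,
    most_active_es,
    sweep_phase_map,
    wm_state_metrics,
)


def fake_result(spike_t, spike_i, duration=1000.0, N_E=400, N_I=100, u_trace=None, x_trace=None, bin_ms=5.0):
    n_bins = int(duration / bin_ms)
    return SimResult(
        spike_t=np.asarray(spike_t, dtype=float),
        spike_i=np.asarray(spike_i, dtype=int),
        duration_ms=duration,
        dt=0.1,
        seed=0,
        bin_ms=bin_ms,
        rec_e=None, rec_i=None, ext=None, leak=None,
        u_trace=u_trace, x_trace=x_trace,
        N_E=N_E, N_I=N_I,
    )


@pytest.fixture(scope="module")
def layout():
    return build_layout(NetworkSpec(N_E=400, N_I=100, p=5, f=0.1, c=0.3))


def population_train(lo, hi, rate_hz, t0, t1):
    """Deterministic raster: each neuron in [lo, hi) fires periodically."""
    period = 1000.0 / rate_hz
    times, ids = [], []
    for i in range(lo, hi):
        t = np.arange(t0 + (i - lo) * period / (hi - lo), t1, period)
        times.append(t)
        ids.append(np.full(t.size, i))
    return np.concatenate(times), np.concatenate(ids)


class TestClassifyPhase:
    def test_quiescent_is_phase1(self, layout):
        res = fake_result([], [])
        assert classify_phase(res, layout) == "phase1"

    def test_single_active_population_is_phase2(self, layout):
        t, i = population_train(*layout.range_of("Es3"), 40.0, 0.0, 1000.0)
        res = fake_result(t, i)
        assert classify_phase(res, layout) == "phase2"
        assert most_active_es(res, layout) == "Es3"

    def test_threshold_boundary_inclusive(self, layout):
        """A population firing exactly at the threshold rate counts as phase2."""
        t, i = population_train(*layout.range_of("Es1"), 10.0, 0.0, 1000.0)
        res = fake_result(t, i)
        assert classify_phase(res, layout, rate_threshold=10.0) == "phase2"

    def test_window_longer_than_run_rejected(self, layout):
        with pytest.raises(ValueError):
            classify_phase(fake_result([], [], duration=400.0), layout, window_ms=500.0)


class TestPersistence:
    def test_sustained_activity_counts_as_held(self, layout):
        crit = PersistenceCriterion(rate_hz=5.0, window_ms=300.0, post_ms=1000.0)
        t, i = population_train(*layout.range_of("Es1"), 20.0, 500.0, 2000.0)
        res = fake_result(t, i, duration=2000.0)
        held, _, _ = check_persistence(res, layout, "Es1", offset_ms=500.0, criterion=crit)
        assert held

    def test_transient_that_dies_is_not_held(self, layout):
        crit = PersistenceCriterion(rate_hz=5.0, window_ms=300.0, post_ms=1000.0)
        t, i = population_train(*layout.range_of("Es1"), 20.0, 500.0, 1200.0)
        res = fake_result(t, i, duration=2000.0)
        held, _, _ = check_persistence(res, layout, "Es1", offset_ms=500.0, criterion=crit)
        assert not held


class TestBisection:
    def test_finds_minimal_succeeding_duration(self):
        calls = []

        def probe(T):
            calls.append(T)
            return T >= 37.0

        found = _bisect_duration(probe, 0.0, 400.0, 1.0)
        assert found == pytest.approx(37.0, abs=1.0)
        assert len(calls) <= 12  # logarithmic, not linear, search

    def test_upper_bound_failure_gives_sentinel(self):
        assert _bisect_duration(lambda T: False, 0.0, 400.0, 1.0) is NOT_LOADABLE
        assert math.isinf(NOT_LOADABLE)

    def test_zero_duration_never_probed_as_success(self):
        # success everywhere: minimal duration collapses to the resolution scale
        found = _bisect_duration(lambda T: True, 0.0, 400.0, 1.0)
        assert 0.0 < found <= 1.0 + 1e-9


class TestStateMetrics:
    def test_frozen_network_rests_at_baselines(self, layout):
        """No spikes: f = 0, u = U, x = X, uxf = 0."""
        n_bins, N_E = 200, 400
        u_tr = np.full((n_bins, N_E), 0.2)
        x_tr = np.full((n_bins, N_E), 1.0)
        res = fake_result([], [], u_trace=u_tr, x_trace=x_tr)
        m = wm_state_metrics(res, layout, "Es1", (0.0, 1000.0))
        assert m.f == (0.0, 0.0)
        assert m.u[0] == pytest.approx(0.2)
        assert m.x[0] == pytest.approx(1.0)
        assert m.ux[0] == pytest.approx(0.2)
        assert m.uxf[0] == 0.0

    def test_rate_and_product_composition(self, layout):
        """ux is the time average of the per-bin product and uxf folds in the
        per-neuron rate."""
        n_bins, N_E = 200, 400
        u_tr = np.full((n_bins, N_E), 0.5)
        x_tr = np.full((n_bins, N_E), 0.4)
        lo, hi = layout.range_of("Es2")
        t, i = population_train(lo, hi, 10.0, 0.0, 1000.0)
        res = fake_result(t, i, u_trace=u_tr, x_trace=x_tr)
        m = wm_state_metrics(res, layout, "Es2", (0.0, 1000.0))
        assert m.f[0] == pytest.approx(10.0, rel=0.01)
        assert m.ux[0] == pytest.approx(0.2)
        assert m.uxf[0] == pytest.approx(2.0, rel=0.01)

    def test_empty_window_rejected(self, layout):
        res = fake_result([], [], u_trace=np.zeros((10, 400)), x_trace=np.zeros((10, 400)))
        with pytest.raises(ValueError):
            wm_state_metrics(res, layout, "Es1", (100.0, 100.0))


class TestPhaseSweep:
    def test_small_grid_runs_and_labels_cells(self, tiny_spec, tiny_table):
        """2x2 sweep: every cell simulated, rates finite, labels consistent."""
        pm = sweep_phase_map(
            tiny_spec, tiny_table,
            a_ee_grid=np.array([0.8, 1.2]), a_ei_grid=np.array([0.9, 1.1]),
            duration_ms=400.0, seed=3, burn_in_ms=100.0,
        )
        assert pm.rate_hz.shape == (2, 2)
        assert np.all(np.isfinite(pm.rate_hz))
        assert pm.failures == []
        assert pm.phase2.dtype == bool
        df = pm.to_frame()
        assert len(df) == 4 and set(df["phase"]) <= {"phase1", "phase2"}
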