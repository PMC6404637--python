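"""Forward-Euler integration of the coupled LIF + short-term-plasticity dynamics.

Membrane dynamics (per neuron class, E or I):

    tau_m dV/dt = -V + I_rec(t) + I_ext(t)

with I_ext Gaussian white noise of mean mu_ext and SD sigma_ext (a
memory-specific stimulus multiplies the target population's mu_ext by the
contrast factor A_cue, leaving sigma_ext unchanged), and I_rec a sum of
delayed delta synapses: a presynaptic spike delivers, after its synapse's
delay, an instantaneous jump of J_ij * u_j * x_j mV for E->E synapses (the
presynaptic facilitation/depression state valid at emission time) or the
static J for all other classes; inhibitory inputs jump the potential
downward.

Discretization (step dt, default 0.1 ms):

    V += (dt/tau)(mu_eff - V) + sigma*sqrt(2*dt/tau)*xi + (arriving jumps)

with xi ~ N(0,1) per neuron per step, so the stationary free-membrane mean is
mu_ext and its SD is sigma_ext independent of dt.  Spike when V >= theta:
reset to V_r and clamp there for the absolute refractory period (arriving
jumps during refractoriness are discarded by default).

Short-term plasticity (per presynaptic excitatory neuron):

    du/dt = (U - u)/tau_u        u <- u + U(1-u)   at each spike
    dx/dt = (X - x)/tau_x        x <- x - u+ * x   at each spike

where the transmitted efficacy uses the post-jump u and the pre-jump x
(Jhat = J * u+ * x).  Facilitation decays slowly (tau_u = 1500 ms) and
resources recover fast (tau_x = 200 ms), which is what lets a selective
population hold a memory.

Recorded per run: the spike raster; per-neuron current traces binned at a
sampling interval (default 5 ms), decomposed into recurrent-excitatory,
recurrent-inhibitory, external (noise + stimulus) and leak channels, each
expressed as the summed membrane-potential increment (mV) contributed in the
bin; and per-neuron bin-averaged STP traces u, x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .network import NetworkSpec, PopulationLayout, SynapseTable, build_layout

__all__ = ["StimulusProtocol", "SimResult", "run", "SimulationError"]


class SimulationError(RuntimeError):
    """Numerical blow-up or recording overflow during integration."""


@dataclass(frozen=True)
class StimulusProtocol:
    """A memory-specific stimulus: raise the target population's external mean.

    During [onset, onset+duration) the target population's mu_ext becomes
    A_cue * mu_ext while sigma_ext is unchanged.
    """

    population: str
    onset_ms: float
    duration_ms: float
    A_cue: float = 1.10

    def __post_init__(self) -> None:
        if self.duration_ms < 0:
            raise ValueError("stimulus duration must be >= 0")
        if self.A_cue < 1:
            raise ValueError("contrast factor A_cue must be >= 1")
        if self.onset_ms < 0:
            raise ValueError("stimulus onset must be >= 0")


@dataclass
class SimResult:
    """Raster, decomposed current traces and STP traces for one run."""

    spike_t: np.ndarray  # spike times, ms
    spike_i: np.ndarray  # neuron indices
    duration_ms: float
    dt: float
    seed: int
    bin_ms: float
    #: (n_bins, N) summed potential increments per channel, or None
    rec_e: np.ndarray | None
    rec_i: np.ndarray | None
    ext: np.ndarray | None
    leak: np.ndarray | None
    #: (n_bins, N_E) bin-averaged STP state, or None
    u_trace: np.ndarray | None
    x_trace: np.ndarray | None
    N_E: int = 0
    N_I: int = 0

    @property
    def n_bins(self) -> int:
        return 0 if self.rec_e is None else self.rec_e.shape[0]

    def bin_times(self) -> np.ndarray:
        """Left edges (ms) of the current/STP sampling bins."""
        return self.bin_ms * np.arange(self.n_bins)

    def spikes_in(self, lo: int, hi: int, t0: float = 0.0, t1: float | None = None):
        """Spike (times, indices) restricted to neuron range [lo, hi) and window."""
        t1 = self.duration_ms if t1 is None else t1
        m = (self.spike_i >= lo) & (self.spike_i < hi) & (self.spike_t >= t0) & (self.spike_t < t1)
        return self.spike_t[m], self.spike_i[m]

    def population_rate(
        self, layout: PopulationLayout, label: str, t0: float = 0.0, t1: float | None = None
    ) -> float:
        """Mean firing rate (Hz) of a population over [t0, t1)."""
        t1 = self.duration_ms if t1 is None else t1
        if t1 <= t0:
            raise ValueError("empty window")
        lo, hi = layout.range_of(label)
        t, _ = self.spikes_in(lo, hi, t0, t1)
        return 1000.0 * t.size / ((t1 - t0) * (hi - lo))

    def rate_trace(
        self, layout: PopulationLayout, label: str, window_ms: float = 100.0, step_ms: float = 10.0
    ):
        """Sliding-window population rate trace: (window centers ms, rates Hz)."""
        lo, hi = layout.range_of(label)
        t, _ = self.spikes_in(lo, hi)
        starts = np.arange(0.0, self.duration_ms - window_ms + 1e-9, step_ms)
        counts = np.searchsorted(np.sort(t), starts + window_ms) - np.searchsorted(
            np.sort(t), starts
        )
        rates = 1000.0 * counts / (window_ms * (hi - lo))
        return starts + window_ms / 2.0, rates

    def raster_frame(self, layout: PopulationLayout | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"time_ms": self.spike_t, "neuron_id": self.spike_i})
        if layout is not None:
            member = layout.membership()
            df["population"] = member[self.spike_i]
        return df

    def raster_to_csv(self, path, layout: PopulationLayout | None = None) -> None:
        self.raster_frame(layout).to_csv(path, index=False)


@njit(cache=True)
def _kernel(
    n_steps,
    N,
    N_E,
    dt,
    tau,
    theta,
    v_r,
    mu_base,
    sigma,
    arp_steps,
    indptr,
    targets,
    weights,
    delay_steps,
    U,
    X,
    tau_u,
    tau_x,
    stim_start,
    stim_stop,
    stim_lo,
    stim_hi,
    stim_mu,
    v0,
    u,
    x,
    seed,
    record,
    steps_per_bin,
    rec_e,
    rec_i,
    ext_tr,
    leak_tr,
    u_tr,
    x_tr,
    spike_t,
    spike_i,
    v_guard,
    discard_refractory,
):
    np.random.seed(seed)
    d_ring = 0
    for s in range(delay_steps.size):
        if delay_steps[s] > d_ring:
            d_ring = delay_steps[s]
    d_ring += 1
    buf_e = np.zeros((d_ring, N))
    buf_i = np.zeros((d_ring, N))
    V = v0.copy()
    ref = np.zeros(N, dtype=np.int64)
    n_spikes = 0
    cap = spike_t.size
    du = dt / tau_u
    dx = dt / tau_x
    n_stim = stim_start.size
    mu_eff = mu_base.copy()
    for t in range(n_steps):
        slot = t % d_ring
        noise = np.random.randn(N)
        b = t // steps_per_bin
        # stimulus gating: rebuild effective means from base each step
        if n_stim > 0:
            for i in range(N):
                mu_eff[i] = mu_base[i]
            for s in range(n_stim):
                if stim_start[s] <= t < stim_stop[s]:
                    for i in range(stim_lo[s], stim_hi[s]):
                        mu_eff[i] = stim_mu[s]
        for i in range(N):
            in_e = buf_e[slot, i]
            in_i = buf_i[slot, i]
            if record:
                rec_e[b, i] += in_e
                rec_i[b, i] += in_i
            if i < N_E:
                u[i] += du * (U - u[i])
                x[i] += dx * (X - x[i])
            if ref[i] > 0:
                ref[i] -= 1
                V[i] = v_r[i]
                if not discard_refractory:
                    V[i] += in_e + in_i  # accumulate-through-refractoriness variant
                if i < N_E and record:
                    u_tr[b, i] += u[i]
                    x_tr[b, i] += x[i]
                continue
            a = dt / tau[i]
            leak = -a * V[i]
            ext = a * mu_eff[i] + sigma[i] * math.sqrt(2.0 * dt / tau[i]) * noise[i]
            V[i] += leak + ext + in_e + in_i
            if record:
                ext_tr[b, i] += ext
                leak_tr[b, i] += leak
            if V[i] >= theta[i]:
                if n_spikes >= cap:
                    return n_spikes, -2  # raster overflow
                spike_t[n_spikes] = t * dt
                spike_i[n_spikes] = i
                n_spikes += 1
                V[i] = v_r[i]
                ref[i] = arp_steps
                if i < N_E:
                    u_plus = u[i] + U * (1.0 - u[i])
                    factor = u_plus * x[i]
                    x[i] -= u_plus * x[i]
                    u[i] = u_plus
                    for s in range(indptr[i], indptr[i + 1]):
                        tgt = targets[s]
                        slot2 = (t + delay_steps[s]) % d_ring
                        if tgt < N_E:
                            buf_e[slot2, tgt] += weights[s] * factor
                        else:
                            buf_e[slot2, tgt] += weights[s]
                else:
                    for s in range(indptr[i], indptr[i + 1]):
                        slot2 = (t + delay_steps[s]) % d_ring
                        buf_i[slot2, targets[s]] -= weights[s]
            elif abs(V[i]) > v_guard:
                return n_spikes, -1  # numerical blow-up
            if i < N_E and record:
                u_tr[b, i] += u[i]
                x_tr[b, i] += x[i]
        for i in range(N):
            buf_e[slot, i] = 0.0
            buf_i[slot, i] = 0.0
    return n_spikes, 0


def run(
    spec: NetworkSpec,
    synapses: SynapseTable,
    da_factors: tuple[float, float] = (1.0, 1.0),
    stimuli: list[StimulusProtocol] | None = None,
    duration_ms: float = 2000.0,
    dt: float = 0.1,
    seed: int | None = None,
    layout: PopulationLayout | None = None,
    record_currents: bool = True,
    bin_ms: float = 5.0,
    v_guard: float = 1000.0,
    discard_refractory_input: bool = True,
    max_rate_hz: float = 500.0,
) -> SimResult:
    """Integrate the network for ``duration_ms`` and record everything.

    ``da_factors = (A_EE, A_EI)`` pre-scales the static efficacies (all E->E
    classes by A_EE, E->I by A_EI).  ``seed`` is mandatory: every run is fully
    reproducible from (structure, stimuli, dt, seed).
    """
    if seed is None:
        raise ValueError("seed is required: runs must be reproducible")
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = int(round(duration_ms / dt))
    if abs(n_steps * dt - duration_ms) > 1e-6:
        raise ValueError("duration must be a multiple of dt")
    layout = layout or build_layout(spec)
    stimuli = stimuli or []
    N, N_E = spec.N, spec.N_E

    tau = np.empty(N)
    theta = np.empty(N)
    v_r = np.empty(N)
    mu = np.empty(N)
    sigma = np.empty(N)
    for arr, pair in ((tau, spec.tau_m), (theta, spec.theta), (v_r, spec.V_r),
                      (mu, spec.mu_ext), (sigma, spec.sigma_ext)):
        arr[:N_E] = pair[0]
        arr[N_E:] = pair[1]

    a_ee, a_ei = da_factors
    weights = synapses.scaled_weights(a_ee, a_ei)
    # re-quantize delays if the run step differs from the table's grid
    if abs(dt - synapses.dt) > 1e-12:
        delay_ms = synapses.delay_steps.astype(np.float64) * synapses.dt
        delay_steps = np.maximum(1, np.ceil(delay_ms / dt - 1e-9)).astype(np.int64)
    else:
        delay_steps = synapses.delay_steps.astype(np.int64)

    stim_start = np.array([int(round(s.onset_ms / dt)) for s in stimuli], dtype=np.int64)
    stim_stop = np.array(
        [int(round((s.onset_ms + s.duration_ms) / dt)) for s in stimuli], dtype=np.int64
    )
    stim_lo = np.array([layout.range_of(s.population)[0] for s in stimuli], dtype=np.int64)
    stim_hi = np.array([layout.range_of(s.population)[1] for s in stimuli], dtype=np.int64)
    stim_mu = np.array(
        [s.A_cue * (spec.mu_ext[0] if layout.range_of(s.population)[1] <= N_E else spec.mu_ext[1])
         for s in stimuli]
    )

    steps_per_bin = max(1, int(round(bin_ms / dt)))
    n_bins = (n_steps + steps_per_bin - 1) // steps_per_bin
    if record_currents:
        rec_e = np.zeros((n_bins, N))
        rec_i = np.zeros((n_bins, N))
        ext_tr = np.zeros((n_bins, N))
        leak_tr = np.zeros((n_bins, N))
        u_tr = np.zeros((n_bins, N_E))
        x_tr = np.zeros((n_bins, N_E))
    else:
        rec_e = rec_i = ext_tr = leak_tr = np.zeros((1, 1))
        u_tr = x_tr = np.zeros((1, 1))

    cap = int(max_rate_hz * N * duration_ms / 1000.0) + 1024
    spike_t = np.empty(cap)
    spike_i = np.empty(cap, dtype=np.int64)

    rng = np.random.default_rng(np.int64(seed) + 0x5F5E100)
    v0 = v_r + rng.random(N) * (theta - v_r)
    u0 = synapses.u.astype(np.float64).copy()
    x0 = synapses.x.astype(np.float64).copy()

    n_spikes, status = _kernel(
        n_steps, N, N_E, dt, tau, theta, v_r, mu, sigma,
        int(round(spec.tau_arp / dt)),
        synapses.indptr.astype(np.int64), synapses.targets.astype(np.int64),
        weights, delay_steps,
        spec.U, spec.X, spec.tau_u, spec.tau_x,
        stim_start, stim_stop, stim_lo, stim_hi, stim_mu,
        v0, u0, x0,
        int(seed) % (2**31 - 1),
        record_currents, steps_per_bin,
        rec_e, rec_i, ext_tr, leak_tr, u_tr, x_tr,
        spike_t, spike_i, v_guard, discard_refractory_input,
    )
    if status == -1:
        raise SimulationError(f"membrane potential exceeded guard bound {v_guard} mV")
    if status == -2:
        raise SimulationError(
            f"spike raster overflow (> {cap} spikes, mean rate above {max_rate_hz} Hz)"
        )

    if record_currents:
        # u/x accumulators -> bin means (last bin may be partial)
        counts = np.full(n_bins, steps_per_bin, dtype=np.float64)
        rem = n_steps - steps_per_bin * (n_bins - 1)
        counts[-1] = rem
        u_tr /= counts[:, None]
        x_tr /= counts[:, None]

    return SimResult(
        spike_t=spike_t[:n_spikes].copy(),
        spike_i=spike_i[:n_spikes].copy(),
        duration_ms=duration_ms,
        dt=dt,
        seed=int(seed),
        bin_ms=steps_per_bin * dt,
        rec_e=rec_e if record_currents else None,
        rec_i=rec_i if record_currents else None,
        ext=ext_tr if record_currents else None,
        leak=leak_tr if record_currents else None,
        u_trace=u_tr if record_currents else None,
        x_trace=x_tr if record_currents else None,
        N_E=N_E,
        N_I=spec.N_I,
    )
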