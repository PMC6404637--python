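"""System-level experiments: phase diagram, item loading/updating, dose-response.

Working memory in this model is a stimulus-driven crossing of the phase
border in the EE-EI gain plane: at rest the network sits in the low-activity
regime (*phase1*); a sufficiently long item-specific stimulus pushes the
facilitated selective population across the border into self-sustained
reverberation (*phase2*), which IS the memory.  The protocols here measure

* the phase map over (A_EE, A_EI) gains: resting rate of the most active
  selective population and the branching parameter, cell by cell;
* T_sens: the minimal stimulus duration that loads an item from rest
  (sensitivity = 1/T_sens), found by bisection;
* T_flexi: the minimal stimulus duration that updates the held item to a new
  one (flexibility = 1 / normalized T_flexi);
* the internal state metrics f, u, x, ux, uxf of the stimulated population.

Success criteria (the persistence rule) are not printed in the source
publication and are explicit, configurable parameters here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import criticality as crit
from .dopamine import DAParams, scaling_factors
from .engine import SimResult, SimulationError, StimulusProtocol, run
from .network import NetworkSpec, PopulationLayout, SynapseTable, build_layout

__all__ = [
    "PersistenceCriterion",
    "WMTrialOutcome",
    "WMStateMetrics",
    "PhaseMap",
    "ImaginaryMemoryError",
    "classify_phase",
    "check_persistence",
    "run_loading_trial",
    "run_update_trial",
    "measure_T_sens",
    "measure_T_flexi",
    "wm_state_metrics",
    "sweep_phase_map",
    "population_sigma",
    "dose_response",
    "calibrate_scaling_range",
    "NOT_LOADABLE",
]

#: sentinel duration for "no stimulus length up to the bound loads the item"
NOT_LOADABLE = math.inf


class ImaginaryMemoryError(RuntimeError):
    """Resting state is already in phase2: spontaneous memory without stimulus."""


@dataclass(frozen=True)
class PersistenceCriterion:
    """An item counts as held when the target population's sliding-window rate
    stays above ``rate_hz`` from ``settle_ms`` after stimulus offset to trial
    end; an update additionally requires the previous population to fall below
    ``off_rate_hz`` over the final ``off_window_ms``.

    Persistent activity in this model is carried by periodic population
    reactivations (one brief high-rate event every ~150-300 ms riding on the
    facilitated synapses) rather than by tonic elevated firing, so the window
    must span at least one reactivation cycle: with the 400 ms default, a held
    item keeps every window above ~4 Hz while the resting state stays below
    ~0.5 Hz, and the 2 Hz threshold separates the two cleanly.  ``post_ms``
    is longer than the facilitation recovery time so that a decaying
    stimulus echo (elevated u without a self-sustaining loop) is not
    mistaken for memory."""

    rate_hz: float = 2.0
    window_ms: float = 400.0
    step_ms: float = 25.0
    settle_ms: float = 200.0
    post_ms: float = 1500.0
    off_rate_hz: float = 2.0
    off_window_ms: float = 400.0


@dataclass
class WMTrialOutcome:
    loaded: bool
    updated: bool | None
    rate_t: np.ndarray
    rate_hz: np.ndarray
    criterion: PersistenceCriterion
    result: SimResult | None = None


@dataclass
class WMStateMetrics:
    """Population mean +/- SD (across neurons) of the internal state over a window."""

    f: tuple[float, float]
    u: tuple[float, float]
    x: tuple[float, float]
    ux: tuple[float, float]
    uxf: tuple[float, float]
    window_ms: tuple[float, float]
    population: str

    def to_dict(self) -> dict:
        return {
            k: {"mean": v[0], "sd": v[1]}
            for k, v in (("f", self.f), ("u", self.u), ("x", self.x), ("ux", self.ux), ("uxf", self.uxf))
        } | {"window_ms": list(self.window_ms), "population": self.population}


@dataclass
class PhaseMap:
    """Resting-state rate and branching parameter over the (A_EE, A_EI) grid."""

    a_ee: np.ndarray
    a_ei: np.ndarray
    rate_hz: np.ndarray  # shape (len(a_ei), len(a_ee))
    sigma: np.ndarray
    phase2: np.ndarray
    rate_threshold: float
    failures: list[tuple[int, int, str]] = field(default_factory=list)

    def border_a_ee(self) -> np.ndarray:
        """Per A_EI row, the smallest grid A_EE already in phase2 (NaN if none)."""
        out = np.full(self.a_ei.size, np.nan)
        for r in range(self.a_ei.size):
            idx = np.flatnonzero(self.phase2[r])
            if idx.size:
                out[r] = self.a_ee[idx[0]]
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r, aei in enumerate(self.a_ei):
            for c, aee in enumerate(self.a_ee):
                rows.append(
                    {"A_EE": aee, "A_EI": aei, "rate_hz": self.rate_hz[r, c],
                     "sigma": self.sigma[r, c], "phase": "phase2" if self.phase2[r, c] else "phase1"}
                )
        return pd.DataFrame(rows)


def classify_phase(
    result: SimResult,
    layout: PopulationLayout,
    rate_threshold: float = 10.0,
    window_ms: float = 500.0,
) -> str:
    """phase2 iff the most active selective population sustains
    ``rate_threshold`` Hz (inclusive) over the final ``window_ms``."""
    if window_ms > result.duration_ms:
        raise ValueError("evaluation window longer than the simulation")
    t0 = result.duration_ms - window_ms
    rates = [result.population_rate(layout, lb, t0) for lb in layout.es_labels]
    return "phase2" if max(rates) >= rate_threshold else "phase1"


def most_active_es(
    result: SimResult, layout: PopulationLayout, t0: float = 0.0, t1: float | None = None
) -> str:
    rates = {lb: result.population_rate(layout, lb, t0, t1) for lb in layout.es_labels}
    return max(rates, key=rates.get)


def check_persistence(
    result: SimResult,
    layout: PopulationLayout,
    label: str,
    offset_ms: float,
    criterion: PersistenceCriterion,
) -> tuple[bool, np.ndarray, np.ndarray]:
    """Apply the persistence rule to a trial; returns (held, t, rate trace)."""
    t, rate = result.rate_trace(layout, label, criterion.window_ms, criterion.step_ms)
    start = offset_ms + criterion.settle_ms
    in_eval = t - criterion.window_ms / 2.0 >= start
    held = bool(in_eval.any()) and bool(np.all(rate[in_eval] >= criterion.rate_hz))
    return held, t, rate


def run_loading_trial(
    spec: NetworkSpec,
    synapses: SynapseTable,
    da_factors: tuple[float, float],
    duration_ms: float,
    A_cue: float = 1.10,
    target: str = "Es1",
    onset_ms: float = 300.0,
    seed: int = 0,
    criterion: PersistenceCriterion | None = None,
    keep_result: bool = False,
    dt: float = 0.1,
) -> WMTrialOutcome:
    """One loading trial: rest, stimulate ``target`` for ``duration_ms``, test
    whether the item persists."""
    criterion = criterion or PersistenceCriterion()
    layout = build_layout(spec)
    offset = onset_ms + duration_ms
    total = offset + criterion.post_ms
    total = math.ceil(total / dt) * dt
    stim = [StimulusProtocol(target, onset_ms, duration_ms, A_cue)] if duration_ms > 0 else []
    result = run(
        spec, synapses, da_factors, stim, total, dt=dt, seed=seed,
        layout=layout, record_currents=False,
    )
    loaded, t, rate = check_persistence(result, layout, target, offset, criterion)
    return WMTrialOutcome(loaded, None, t, rate, criterion, result if keep_result else None)


def run_update_trial(
    spec: NetworkSpec,
    synapses: SynapseTable,
    da_factors: tuple[float, float],
    duration_ms: float,
    A_cue: float = 1.10,
    source: str = "Es1",
    target: str = "Es2",
    load_ms: float = 300.0,
    hold_ms: float = 500.0,
    onset_ms: float = 300.0,
    seed: int = 0,
    criterion: PersistenceCriterion | None = None,
    dt: float = 0.1,
) -> WMTrialOutcome:
    """Load ``source`` with a generous stimulus, then probe whether a
    ``duration_ms`` stimulus to ``target`` overwrites it."""
    criterion = criterion or PersistenceCriterion()
    layout = build_layout(spec)
    onset2 = onset_ms + load_ms + hold_ms
    offset2 = onset2 + duration_ms
    total = math.ceil((offset2 + criterion.post_ms) / dt) * dt
    stims = [StimulusProtocol(source, onset_ms, load_ms, A_cue)]
    if duration_ms > 0:
        stims.append(StimulusProtocol(target, onset2, duration_ms, A_cue))
    result = run(
        spec, synapses, da_factors, stims, total, dt=dt, seed=seed,
        layout=layout, record_currents=False,
    )
    # the source item must actually be held right before the update probe
    pre_rate = result.population_rate(layout, source, onset2 - criterion.off_window_ms, onset2)
    src_loaded = pre_rate >= criterion.rate_hz
    tgt_loaded, t, rate = check_persistence(result, layout, target, offset2, criterion)
    src_off = (
        result.population_rate(layout, source, total - criterion.off_window_ms, total)
        < criterion.off_rate_hz
    )
    updated = bool(src_loaded and tgt_loaded and src_off)
    return WMTrialOutcome(src_loaded, updated, t, rate, criterion)


def _bisect_duration(
    probe,
    lower_ms: float,
    upper_ms: float,
    resolution_ms: float,
) -> float:
    """Minimal duration in (lower, upper] for which ``probe`` succeeds,
    assuming monotone success; NOT_LOADABLE when the upper bound fails."""
    if not probe(upper_ms):
        return NOT_LOADABLE
    lo, hi = lower_ms, upper_ms  # lo fails (or is 0), hi succeeds
    while hi - lo > resolution_ms:
        mid = (lo + hi) / 2.0
        mid = round(mid / resolution_ms) * resolution_ms
        if mid <= lo or mid >= hi:
            break
        if probe(mid):
            hi = mid
        else:
            lo = mid
    return hi


def _majority(flags: list[bool]) -> bool:
    return sum(flags) * 2 > len(flags)


def _majority_over(trial, seeds: list[int]) -> bool:
    """Majority vote over per-seed trials, stopping as soon as it is decided."""
    k = len(seeds)
    need = k // 2 + 1
    yes = no = 0
    for s in seeds:
        if trial(s):
            yes += 1
        else:
            no += 1
        if yes >= need:
            return True
        if no >= need:
            return False
    return yes * 2 > k


def measure_T_sens(
    spec: NetworkSpec,
    synapses: SynapseTable,
    da_factors: tuple[float, float],
    A_cue: float = 1.10,
    bounds_ms: tuple[float, float] = (0.0, 400.0),
    resolution_ms: float = 1.0,
    k_seeds: int = 3,
    seed: int = 0,
    target: str = "Es1",
    criterion: PersistenceCriterion | None = None,
    check_resting: bool = True,
    dt: float = 0.1,
) -> float:
    """Shortest stimulus duration (ms) that loads an item, by bisection.

    Success at each probed duration is decided by majority over ``k_seeds``
    trials (the same seed list at every probe).  Returns ``NOT_LOADABLE``
    when even the upper duration bound fails.  Raises
    :class:`ImaginaryMemoryError` when the resting state is already phase2.
    """
    criterion = criterion or PersistenceCriterion()
    layout = build_layout(spec)
    if check_resting:
        # near-border resting states flicker across the classification
        # threshold seed-to-seed; abort only when phase2 is the majority
        n_check = max(3, k_seeds)
        phase2_votes = 0
        for k in range(n_check):
            rest = run(spec, synapses, da_factors, [], 1000.0, dt=dt,
                       seed=seed + 7919 * (k + 1), layout=layout,
                       record_currents=False)
            phase2_votes += classify_phase(rest, layout) == "phase2"
        if phase2_votes * 2 > n_check:
            raise ImaginaryMemoryError(
                "resting state is phase2 (imaginary memory): T_sens undefined"
            )
    seeds = [seed + 1 + k for k in range(k_seeds)]

    def probe(T: float) -> bool:
        return _majority_over(
            lambda s: run_loading_trial(
                spec, synapses, da_factors, T, A_cue, target,
                seed=s, criterion=criterion, dt=dt,
            ).loaded,
            seeds,
        )

    return _bisect_duration(probe, bounds_ms[0], bounds_ms[1], resolution_ms)


def measure_T_flexi(
    spec: NetworkSpec,
    synapses: SynapseTable,
    da_factors: tuple[float, float],
    A_cue: float = 1.10,
    bounds_ms: tuple[float, float] = (0.0, 400.0),
    resolution_ms: float = 1.0,
    k_seeds: int = 3,
    seed: int = 0,
    source: str = "Es1",
    target: str = "Es2",
    criterion: PersistenceCriterion | None = None,
    dt: float = 0.1,
) -> float:
    """Shortest stimulus duration (ms) that updates the held item, by bisection."""
    criterion = criterion or PersistenceCriterion()
    seeds = [seed + 1 + k for k in range(k_seeds)]

    def probe(T: float) -> bool:
        return _majority_over(
            lambda s: run_update_trial(
                spec, synapses, da_factors, T, A_cue, source, target,
                seed=s, criterion=criterion, dt=dt,
            ).updated,
            seeds,
        )

    return _bisect_duration(probe, bounds_ms[0], bounds_ms[1], resolution_ms)


def wm_state_metrics(
    result: SimResult,
    layout: PopulationLayout,
    population: str = "Es1",
    window_ms: tuple[float, float] | None = None,
) -> WMStateMetrics:
    """Mean +/- SD across neurons of rate f (Hz), u, x, ux and uxf = u*x*f.

    u and x are time-averaged per neuron over the window; ux is the time
    average of the per-bin product; uxf multiplies it by the per-neuron rate
    (total transmitter used per second).
    """
    if result.u_trace is None:
        raise ValueError("STP traces not recorded: run with record_currents=True")
    t0, t1 = window_ms if window_ms is not None else (0.0, result.duration_ms)
    if t1 <= t0:
        raise ValueError("empty window")
    b0 = int(t0 // result.bin_ms)
    b1 = max(b0 + 1, int(math.ceil(t1 / result.bin_ms)))
    lo, hi = layout.range_of(population)
    if hi > result.N_E:
        raise ValueError(f"{population} is not an excitatory population")
    u = result.u_trace[b0:b1, lo:hi]
    x = result.x_trace[b0:b1, lo:hi]
    st, si = result.spikes_in(lo, hi, t0, t1)
    counts = np.bincount(si - lo, minlength=hi - lo)
    f = counts * 1000.0 / (t1 - t0)
    u_n = u.mean(axis=0)
    x_n = x.mean(axis=0)
    ux_n = (u * x).mean(axis=0)
    uxf_n = ux_n * f

    def ms(a):
        return float(a.mean()), float(a.std(ddof=1)) if a.size > 1 else 0.0

    return WMStateMetrics(
        f=ms(f), u=ms(u_n), x=ms(x_n), ux=ms(ux_n), uxf=ms(uxf_n),
        window_ms=(t0, t1), population=population,
    )


def population_sigma(
    result: SimResult,
    layout: PopulationLayout,
    t0: float = 0.0,
    bin_ms: float | None = None,
    min_spikes: int = 20,
) -> float:
    """Branching parameter of the most active selective population's resting
    activity; adaptive bin width (2x mean inter-event interval) when
    ``bin_ms`` is None.  Returns 0 for (near-)silent rasters."""
    label = most_active_es(result, layout, t0)
    lo, hi = layout.range_of(label)
    t, _ = result.spikes_in(lo, hi, t0)
    if t.size < min_spikes:
        return 0.0
    width = bin_ms if bin_ms is not None else crit.adaptive_bin_width(t)
    av = crit.detect_avalanches(t, width, population=label)
    if av.n_avalanches == 0:
        return 0.0
    return crit.branching_parameter(av).sigma


def sweep_phase_map(
    spec: NetworkSpec,
    synapses: SynapseTable,
    a_ee_grid: np.ndarray,
    a_ei_grid: np.ndarray,
    duration_ms: float = 1500.0,
    seed: int = 0,
    rate_threshold: float = 10.0,
    burn_in_ms: float = 500.0,
    common_seed: bool = True,
    dt: float = 0.1,
) -> PhaseMap:
    """One resting simulation per (A_EE, A_EI) grid cell; per-cell failures are
    recorded, not raised.  ``common_seed`` reuses one seed across cells so the
    map varies only through the gains."""
    layout = build_layout(spec)
    a_ee_grid = np.asarray(a_ee_grid, dtype=float)
    a_ei_grid = np.asarray(a_ei_grid, dtype=float)
    rate = np.full((a_ei_grid.size, a_ee_grid.size), np.nan)
    sig = np.full_like(rate, np.nan)
    phase2 = np.zeros(rate.shape, dtype=bool)
    failures: list[tuple[int, int, str]] = []
    for r, aei in enumerate(a_ei_grid):
        for c, aee in enumerate(a_ee_grid):
            cell_seed = seed if common_seed else seed + 1000 * r + c
            try:
                res = run(
                    spec, synapses, (aee, aei), [], duration_ms, dt=dt,
                    seed=cell_seed, layout=layout, record_currents=False,
                )
                label = most_active_es(res, layout, burn_in_ms)
                rate[r, c] = res.population_rate(layout, label, burn_in_ms)
                sig[r, c] = population_sigma(res, layout, burn_in_ms)
                window = min(500.0, duration_ms - burn_in_ms)
                phase2[r, c] = classify_phase(res, layout, rate_threshold, window) == "phase2"
            except SimulationError as exc:  # pragma: no cover - guard path
                failures.append((r, c, str(exc)))
    return PhaseMap(a_ee_grid, a_ei_grid, rate, sig, phase2, rate_threshold, failures)


def calibrate_scaling_range(
    spec: NetworkSpec,
    synapses: SynapseTable,
    depth: float = 0.5,
    base: DAParams | None = None,
    bounds: tuple[float, float] = (0.90, 1.40),
    resolution: float = 0.005,
    duration_ms: float = 1500.0,
    seeds: tuple[int, ...] = (0, 1, 2),
    rate_threshold: float = 2.0,
    margin: float = 0.01,
    dt: float = 0.1,
) -> DAParams:
    """Choose [A_min, A_max] so the resting state at D_0 sits just on the
    quiet (phase1) side of the transition.

    With the modulation depth ``D_L = A_max - A_min`` fixed, the resting
    operating point at D_0 scales essentially with A_min, so A_min is bisected
    to the largest value whose resting runs (all ``seeds``) stay below
    ``rate_threshold``, then backed off by ``margin``.  This mirrors the
    published trajectory-design objective: maximal sensitivity without
    risking imaginary memory.

    The default threshold (2 Hz) marks the *onset of collective spontaneous
    activity* of the most active selective population, which in finite
    networks is where the transition rounds off and spontaneous avalanches
    become scale-free; the self-sustained (>= 10 Hz) ignition level lies
    beyond it, inside the regime where spontaneous one-population dominance
    (imaginary memory) is already frequent.
    """
    base = base or DAParams()
    layout = build_layout(spec)

    def resting_is_phase1(a_min: float) -> bool:
        params = replace(base, A_min=a_min, A_max=a_min + depth)
        factors = scaling_factors(params.D_0, params)
        for s in seeds:
            res = run(spec, synapses, factors, [], duration_ms, dt=dt, seed=s,
                      layout=layout, record_currents=False)
            if classify_phase(res, layout, rate_threshold) == "phase2":
                return False
        return True

    lo, hi = bounds
    if not resting_is_phase1(lo):
        raise ImaginaryMemoryError(f"lower calibration bound A_min={lo} is already phase2")
    if resting_is_phase1(hi):
        a_min = hi  # border above the scan range; use the top
    else:
        while hi - lo > resolution:
            mid = (lo + hi) / 2.0
            if resting_is_phase1(mid):
                lo = mid
            else:
                hi = mid
        a_min = lo
    a_min = round((a_min - margin) / resolution) * resolution
    return replace(base, A_min=a_min, A_max=a_min + depth)


def dose_response(
    spec: NetworkSpec,
    synapses: SynapseTable,
    params: DAParams,
    D_grid: np.ndarray,
    A_cue: float = 1.10,
    seed: int = 0,
    k_seeds: int = 3,
    resolution_ms: float = 1.0,
    bounds_ms: tuple[float, float] = (0.0, 400.0),
    with_flexibility: bool = True,
    metrics_stim_ms: float = 200.0,
    dt: float = 0.1,
) -> pd.DataFrame:
    """T_sens, T_flexi and internal state metrics per D1 activation level.

    One row per grid level with columns T_sens_ms, sensitivity_per_ms,
    T_flexi_ms, T_flexi_norm, flexibility, and the f/u/x/ux/uxf means and SDs
    of the stimulated population during a fixed 200 ms strength1 stimulus.
    Normalization of T_flexi (and the flexibility reciprocal) is relative to
    the smallest T_flexi on the grid.
    """
    layout = build_layout(spec)
    rows = []
    for D in np.asarray(D_grid, dtype=float):
        factors = scaling_factors(D, params)
        row: dict = {"D": D, "A_EE": factors[0], "A_EI": factors[1]}
        try:
            row["T_sens_ms"] = measure_T_sens(
                spec, synapses, factors, A_cue, bounds_ms, resolution_ms,
                k_seeds, seed, dt=dt,
            )
        except ImaginaryMemoryError:
            row["T_sens_ms"] = np.nan
        row["sensitivity_per_ms"] = (
            1.0 / row["T_sens_ms"] if np.isfinite(row["T_sens_ms"]) and row["T_sens_ms"] > 0 else 0.0
        )
        if with_flexibility:
            row["T_flexi_ms"] = measure_T_flexi(
                spec, synapses, factors, A_cue, bounds_ms, resolution_ms,
                k_seeds, seed, dt=dt,
            )
        onset = 300.0
        res = run(
            spec, synapses, factors,
            [StimulusProtocol("Es1", onset, metrics_stim_ms, A_cue)],
            math.ceil((onset + metrics_stim_ms + 200.0) / dt) * dt,
            dt=dt, seed=seed, layout=layout, record_currents=True,
        )
        m = wm_state_metrics(res, layout, "Es1", (onset, onset + metrics_stim_ms))
        for k, v in (("f", m.f), ("u", m.u), ("x", m.x), ("ux", m.ux), ("uxf", m.uxf)):
            row[f"{k}_mean"], row[f"{k}_sd"] = v
        rows.append(row)
    df = pd.DataFrame(rows)
    if with_flexibility:
        finite = df["T_flexi_ms"].replace(NOT_LOADABLE, np.nan)
        t_min = finite.min()
        df["T_flexi_norm"] = finite / t_min if t_min and np.isfinite(t_min) else np.nan
        df["flexibility"] = 1.0 / df["T_flexi_norm"]
    return df
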