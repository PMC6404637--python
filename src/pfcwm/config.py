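"""Experiment configuration, orchestration, serialization and provenance.

An :class:`ExperimentConfig` fully determines a run together with its seeds:
it bundles the network spec, the dopamine parameters, protocol settings and
analysis settings, round-trips losslessly through YAML, and hashes stably so
every output artifact can be traced back to (config hash, seed set).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dopamine import DAParams, build_trajectory, scaling_factors
from .engine import StimulusProtocol, run
from .network import NetworkSpec, build_layout, sample_connectivity
from . import balance as bal
from . import criticality as crit
from . import protocols as proto

__all__ = ["ExperimentConfig", "ConfigError", "load_config", "run_experiment"]


class ConfigError(ValueError):
    """Schema violation; the message names the offending field path."""


@dataclass(frozen=True)
class ProtocolSettings:
    A_cue: float = 1.10
    D_grid: tuple[float, ...] = (0.6, 0.8, 1.0, 1.2, 1.4)
    k_seeds: int = 3
    resolution_ms: float = 1.0
    bounds_ms: tuple[float, float] = (0.0, 400.0)
    burn_in_ms: float = 200.0


@dataclass(frozen=True)
class AnalysisSettings:
    avalanche_bin_ms: float | None = None  # None = adaptive (2x mean IEI)
    bins_per_decade: int = 10
    current_bin_ms: float = 5.0
    n_trials: int = 15
    phase_grid_n: int = 5


@dataclass(frozen=True)
class ExperimentConfig:
    network: NetworkSpec = field(default_factory=NetworkSpec)
    dopamine: DAParams = field(default_factory=DAParams)
    protocol: ProtocolSettings = field(default_factory=ProtocolSettings)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)
    seed: int = 0
    duration_ms: float = 2000.0
    dt: float = 0.1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=True))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(_plain(self.to_dict()), sort_keys=True).encode()
        ).hexdigest()[:16]


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


_SECTIONS = {
    "network": NetworkSpec,
    "dopamine": DAParams,
    "protocol": ProtocolSettings,
    "analysis": AnalysisSettings,
}
_TUPLE_FIELDS = {
    "theta", "V_r", "tau_m", "mu_ext", "sigma_ext", "delay_range",
    "D_grid", "bounds_ms",
}


def load_config(path) -> ExperimentConfig:
    """Read and schema-validate a YAML experiment configuration.

    Unknown keys and invalid values raise :class:`ConfigError` naming the
    field path (e.g. ``network.f``).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top level must be a mapping")
    kwargs: dict = {}
    for section, cls in _SECTIONS.items():
        sub = raw.pop(section, {})
        if not isinstance(sub, dict):
            raise ConfigError(f"{section}: must be a mapping")
        names = {f.name for f in dataclasses.fields(cls)}
        for key in sub:
            if key not in names:
                raise ConfigError(f"{section}.{key}: unknown field")
        sub = {k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
               for k, v in sub.items()}
        try:
            kwargs[section] = cls(**sub)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{section}: {exc}") from exc
    for key in ("seed", "duration_ms", "dt"):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if raw:
        raise ConfigError(f"unknown top-level field(s): {sorted(raw)}")
    try:
        return ExperimentConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def run_experiment(
    config: ExperimentConfig,
    stages: list[str],
    out_dir,
) -> dict:
    """Execute the requested stages and write artifacts plus a manifest.

    Stages: ``trajectory``, ``simulate``, ``phase-sweep``, ``avalanche-fit``,
    ``balance``, ``dose-response``.  The manifest records the config hash,
    software version, seeds and per-stage outputs or failures.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec, da = config.network, config.dopamine
    layout = build_layout(spec)
    manifest: dict = {
        "config_hash": config.hash(),
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }
    config.to_yaml(out / "config.yaml")
    synapses = None

    def table():
        nonlocal synapses
        if synapses is None:
            synapses = sample_connectivity(spec, layout, config.seed, config.dt)
        return synapses

    for stage in stages:
        entry: dict = {"outputs": []}
        try:
            if stage == "trajectory":
                prof = build_trajectory(da)
                prof.to_csv(out / "trajectory.csv")
                entry["outputs"].append("trajectory.csv")
                entry["argmax_dA"] = prof.argmax_dA()
            elif stage == "simulate":
                factors = scaling_factors(da.D_0, da)
                res = run(spec, table(), factors, [], config.duration_ms,
                          config.dt, config.seed, layout=layout,
                          bin_ms=config.analysis.current_bin_ms)
                res.raster_to_csv(out / "raster.csv", layout)
                entry["outputs"].append("raster.csv")
                entry["n_spikes"] = int(res.spike_t.size)
                entry["n_simulations"] = 1
            elif stage == "phase-sweep":
                grid_ee = np.round(np.linspace(da.A_min, da.A_max, config.analysis.phase_grid_n), 6)
                grid_ei = grid_ee.copy()
                pm = proto.sweep_phase_map(spec, table(), grid_ee, grid_ei,
                                           seed=config.seed, dt=config.dt)
                pm.to_frame().to_csv(out / "phase_map.csv", index=False)
                entry["outputs"].append("phase_map.csv")
                entry["n_simulations"] = int(grid_ee.size * grid_ei.size)
                entry["failures"] = pm.failures
            elif stage == "avalanche-fit":
                factors = scaling_factors(da.D_0, da)
                res = run(spec, table(), factors, [], config.duration_ms,
                          config.dt, config.seed, layout=layout,
                          record_currents=False)
                label = proto.most_active_es(res, layout, config.protocol.burn_in_ms)
                lo, hi = layout.range_of(label)
                t, _ = res.spikes_in(lo, hi, config.protocol.burn_in_ms)
                width = config.analysis.avalanche_bin_ms or crit.adaptive_bin_width(t)
                av = crit.detect_avalanches(t, width, population=label)
                fit = crit.fit_power_law(av.sizes, config.analysis.bins_per_decade)
                sigma = crit.branching_parameter(av).sigma
                report = {
                    "population": label, "bin_ms": width, "alpha": fit.alpha,
                    "ks": fit.ks, "range": [fit.s_min, fit.s_max],
                    "n": av.n_avalanches, "sigma": sigma,
                }
                (out / "avalanche_fit.json").write_text(json.dumps(report, indent=2))
                entry["outputs"].append("avalanche_fit.json")
                entry.update(report)
            elif stage == "balance":
                factors = scaling_factors(da.D_0, da)
                onset, dur = 300.0, 200.0
                res = run(spec, table(), factors,
                          [StimulusProtocol("Es1", onset, dur, config.protocol.A_cue)],
                          onset + dur + 200.0, config.dt, config.seed,
                          layout=layout, bin_ms=config.analysis.current_bin_ms)
                report = {}
                for variant in ("total", "recurrent_only"):
                    bm = bal.population_balance(res, layout, variant, (onset, onset + dur))
                    report[variant] = bm.to_dict()
                (out / "balance.json").write_text(json.dumps(report, indent=2))
                entry["outputs"].append("balance.json")
            elif stage == "dose-response":
                df = proto.dose_response(
                    spec, table(), da, np.array(config.protocol.D_grid),
                    config.protocol.A_cue, config.seed,
                    config.protocol.k_seeds, config.protocol.resolution_ms,
                    config.protocol.bounds_ms, dt=config.dt,
                )
                df.to_csv(out / "dose_response.csv", index=False)
                entry["outputs"].append("dose_response.csv")
            else:
                raise ConfigError(f"unknown stage {stage!r}")
        except Exception as exc:  # per-stage failures land in the manifest
            if isinstance(exc, ConfigError):
                raise
            entry["error"] = f"{type(exc).__name__}: {exc}"
        manifest["stages"][stage] = entry
    (out / "manifest.json").write_text(json.dumps(_plain(manifest), indent=2))
    return manifest
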