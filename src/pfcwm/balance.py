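"""Cellular-level E/I balance: current correlations and spike-train regularity.

A neuron is "balanced" when its inhibitory input tracks its excitatory input;
the tracking is quantified by the magnitude of the Pearson correlation between
the two binned current traces (inhibitory currents are negative, so the raw
coefficient is negative; its absolute value is reported).  Two trace variants
are analyzed:

* ``total``:          excitatory = recurrent-E + external (noise + stimulus),
                      inhibitory = recurrent-I + leak;
* ``recurrent_only``: recurrent-E vs recurrent-I.

Irregularity of spiking is quantified by the coefficient of variation
CV = sigma/mu of the inter-spike-interval distribution; a balanced,
fluctuation-driven regime has CV near (or above) 1, a mean-driven regular
regime has CV near 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import SimResult
from .network import PopulationLayout

__all__ = ["BalanceMetrics", "ISIStats", "ei_correlation", "population_balance", "isi_cv"]


@dataclass
class BalanceMetrics:
    """Per-population |rho| summaries for one trace variant and window."""

    variant: str
    window_ms: tuple[float, float]
    bin_ms: float
    #: per-population arrays of per-neuron |rho| (NaN where undefined)
    per_neuron: dict[str, np.ndarray]
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, r in self.per_neuron.items():
            ok = r[~np.isnan(r)]
            self.mean[label] = float(ok.mean()) if ok.size else math.nan
            self.sd[label] = float(ok.std(ddof=1)) if ok.size > 1 else math.nan

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "window_ms": list(self.window_ms),
            "bin_ms": self.bin_ms,
            "mean_abs_rho": self.mean,
            "sd_abs_rho": self.sd,
        }


@dataclass
class ISIStats:
    intervals: np.ndarray
    mean: float
    sd: float
    cv: float

    @property
    def n(self) -> int:
        return int(self.intervals.size)


def ei_correlation(e_trace: np.ndarray, i_trace: np.ndarray, formula: str = "pearson") -> float:
    """|rho| between an excitatory and an inhibitory current trace.

    ``formula="pearson"`` is the standard product-moment coefficient
    (covariance over the product of SDs).  ``formula="printed"`` divides the
    covariance by the *sum of variances* instead; it is kept only for audit
    (it is not bounded by 1 and is not a correlation).  Returns NaN when
    either trace is constant.
    """
    e = np.asarray(e_trace, dtype=float)
    i = np.asarray(i_trace, dtype=float)
    if e.shape != i.shape or e.ndim != 1:
        raise ValueError("traces must be 1-D and equal length")
    if e.size < 3:
        raise ValueError("need at least 3 samples")
    ve, vi = e.var(), i.var()
    if ve == 0.0 or vi == 0.0:
        return math.nan
    cov = float(np.mean((e - e.mean()) * (i - i.mean())))
    if formula == "pearson":
        return abs(cov / math.sqrt(ve * vi))
    if formula == "printed":
        return abs(cov / (ve + vi))
    raise ValueError(f"unknown formula {formula!r}")


def _channel_traces(result: SimResult, variant: str, exclude_leak: bool = False):
    for name in ("rec_e", "rec_i", "ext", "leak"):
        if getattr(result, name) is None:
            raise ValueError(f"missing current channel {name!r}: run with record_currents=True")
    if variant == "recurrent_only":
        return result.rec_e, result.rec_i
    if variant == "total":
        e = result.rec_e + result.ext
        i = result.rec_i if exclude_leak else result.rec_i + result.leak
        return e, i
    raise ValueError(f"unknown variant {variant!r}")


def population_balance(
    result: SimResult,
    layout: PopulationLayout,
    variant: str = "total",
    window_ms: tuple[float, float] | None = None,
    populations: tuple[str, ...] | None = None,
    exclude_leak: bool = False,
    formula: str = "pearson",
) -> BalanceMetrics:
    """Per-neuron E/I current correlation, summarized per population.

    The window should cover the interval of interest (for stimulus-evoked
    analyses, the stimulus presentation); it is expressed in ms and snapped
    to the current-sampling bins.
    """
    e_all, i_all = _channel_traces(result, variant, exclude_leak)
    n_bins = e_all.shape[0]
    if window_ms is None:
        b0, b1 = 0, n_bins
    else:
        b0 = int(window_ms[0] // result.bin_ms)
        b1 = int(math.ceil(window_ms[1] / result.bin_ms))
        if not 0 <= b0 < b1 <= n_bins:
            raise ValueError(f"window {window_ms} outside the recorded {n_bins} bins")
    populations = populations or layout.labels
    per_neuron: dict[str, np.ndarray] = {}
    for label in populations:
        lo, hi = layout.range_of(label)
        e = e_all[b0:b1, lo:hi]
        i = i_all[b0:b1, lo:hi]
        ec = e - e.mean(axis=0)
        ic = i - i.mean(axis=0)
        se = ec.std(axis=0)
        si = ic.std(axis=0)
        cov = (ec * ic).mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            if formula == "pearson":
                rho = cov / (se * si)
            else:
                rho = cov / (se**2 + si**2)
        rho[(se == 0) | (si == 0)] = np.nan
        per_neuron[label] = np.abs(rho)
    win = (b0 * result.bin_ms, b1 * result.bin_ms)
    return BalanceMetrics(variant=variant, window_ms=win, bin_ms=result.bin_ms, per_neuron=per_neuron)


def isi_cv(
    spike_times_ms: np.ndarray,
    spike_ids: np.ndarray,
    window_ms: tuple[float, float] | None = None,
    per_neuron_average: bool = False,
) -> ISIStats:
    """CV = sigma/mu of the inter-spike-interval distribution of a population.

    ISIs are computed within neurons and pooled by default; with
    ``per_neuron_average=True`` the CV is computed per neuron (those with >= 2
    ISIs) and averaged.
    """
    t = np.asarray(spike_times_ms, dtype=float)
    ids = np.asarray(spike_ids)
    if window_ms is not None:
        m = (t >= window_ms[0]) & (t < window_ms[1])
        t, ids = t[m], ids[m]
    order = np.lexsort((t, ids))
    t, ids = t[order], ids[order]
    same = ids[1:] == ids[:-1]
    isis = np.diff(t)[same]
    isis = isis[isis > 0]
    if isis.size < 2:
        raise ValueError("need at least 2 inter-spike intervals")
    if per_neuron_average:
        nid = ids[1:][same & (np.diff(t) > 0)]
        cvs = []
        for n in np.unique(nid):
            x = isis[nid == n]
            if x.size >= 2 and x.mean() > 0:
                cvs.append(x.std(ddof=1) / x.mean())
        if not cvs:
            raise ValueError("no neuron has enough intervals")
        cv = float(np.mean(cvs))
        return ISIStats(intervals=isis, mean=float(isis.mean()), sd=float(isis.std(ddof=1)), cv=cv)
    mu = float(isis.mean())
    sd = float(isis.std(ddof=1))
    return ISIStats(intervals=isis, mean=mu, sd=sd, cv=sd / mu)
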