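"""Neuronal avalanches: detection, power-law exponent fitting, branching parameter.

An avalanche is a maximal run of consecutive non-empty time bins of a
population's spike train; its size s is the number of spikes in the run.  In a
critical network the size distribution follows P(s) ~ s^alpha with alpha close
to -1.5, and the branching parameter

    sigma = < Descendants / Ancestors >

(the mean over avalanches of second-bin count over first-bin count) is close
to 1: each spike triggers on average one successor.

The exponent is fitted the way avalanche studies usually plot it: the
empirical density is smoothed by logarithmic binning with geometric-mean bin
centers, candidate size ranges are scored by the Kolmogorov-Smirnov distance
between the in-range data and the power-law candidate, the minimal-KS range is
kept, and alpha is the least-squares slope of the smoothed points in log-log
coordinates over that range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AvalancheSet",
    "PowerLawFit",
    "BranchingEstimate",
    "detect_avalanches",
    "adaptive_bin_width",
    "fit_power_law",
    "branching_parameter",
]


@dataclass
class AvalancheSet:
    """Avalanches of one population's raster at bin width ``bin_ms``.

    ``bin_counts`` concatenates the per-bin spike counts of all avalanches;
    ``offsets`` (CSR-style) delimits them: avalanche k occupies
    ``bin_counts[offsets[k]:offsets[k+1]]``.
    """

    bin_ms: float
    bin_counts: np.ndarray
    offsets: np.ndarray
    population: str = ""

    @property
    def n_avalanches(self) -> int:
        return int(self.offsets.size - 1)

    @property
    def sizes(self) -> np.ndarray:
        return np.add.reduceat(self.bin_counts, self.offsets[:-1]) if self.n_avalanches else np.empty(0, dtype=np.int64)

    @property
    def durations(self) -> np.ndarray:
        """Avalanche durations in bins."""
        return np.diff(self.offsets)

    def first_second_bins(self) -> tuple[np.ndarray, np.ndarray]:
        """(Ancestors, Descendants) per avalanche; Descendants=0 for single-bin."""
        first = self.bin_counts[self.offsets[:-1]]
        lengths = np.diff(self.offsets)
        second = np.where(lengths > 1, self.bin_counts[np.minimum(self.offsets[:-1] + 1, self.bin_counts.size - 1)], 0)
        return first, second

    @property
    def total_spikes(self) -> int:
        return int(self.bin_counts.sum())


@dataclass
class PowerLawFit:
    """Least-squares power-law fit over the KS-optimal size range."""

    alpha: float
    s_min: float
    s_max: float
    ks: float
    n_in_range: int
    #: smoothed density support points: geometric-mean centers and densities
    centers: np.ndarray
    density: np.ndarray
    low_count: bool = False


@dataclass
class BranchingEstimate:
    sigma: float
    ancestors: np.ndarray
    descendants: np.ndarray
    n_single_bin: int

    @property
    def n_avalanches(self) -> int:
        return int(self.ancestors.size)


def adaptive_bin_width(spike_times_ms: np.ndarray, factor: float = 2.0) -> float:
    """Bin width as ``factor`` times the mean population inter-event interval.

    This is how the canonical 0.3 ms value arises in the full-size network;
    at reduced population sizes the same rule keeps the binning statistics
    comparable.
    """
    t = np.sort(np.asarray(spike_times_ms, dtype=float))
    if t.size < 2:
        raise ValueError("need at least 2 spikes for an adaptive bin width")
    iei = np.diff(t)
    return factor * float(iei.mean())


def detect_avalanches(
    spike_times_ms: np.ndarray,
    bin_ms: float = 0.3,
    t0: float | None = None,
    t1: float | None = None,
    population: str = "",
) -> AvalancheSet:
    """Bin a population's spikes and extract maximal runs of non-empty bins.

    Bins are half-open ``[t0 + k*bin_ms, t0 + (k+1)*bin_ms)``.  An empty
    raster yields an empty set (not an error).
    """
    if bin_ms <= 0:
        raise ValueError("bin width must be positive")
    t = np.asarray(spike_times_ms, dtype=float)
    if t0 is not None or t1 is not None:
        lo = -np.inf if t0 is None else t0
        hi = np.inf if t1 is None else t1
        t = t[(t >= lo) & (t < hi)]
    if t.size == 0:
        return AvalancheSet(bin_ms, np.empty(0, dtype=np.int64), np.zeros(1, dtype=np.int64), population)
    start = float(t.min()) if t0 is None else float(t0)
    idx = np.floor((t - start) / bin_ms).astype(np.int64)
    counts = np.bincount(idx)
    active = counts > 0
    # run boundaries of the active mask
    edges = np.diff(np.concatenate(([0], active.view(np.int8), [0])))
    run_starts = np.flatnonzero(edges == 1)
    run_stops = np.flatnonzero(edges == -1)
    bin_counts = []
    offsets = [0]
    for a, b in zip(run_starts, run_stops):
        bin_counts.append(counts[a:b])
        offsets.append(offsets[-1] + (b - a))
    return AvalancheSet(
        bin_ms,
        np.concatenate(bin_counts).astype(np.int64),
        np.asarray(offsets, dtype=np.int64),
        population,
    )


def _log_binned_density(sizes: np.ndarray, bins_per_decade: int):
    """Histogram sizes into logarithmic bins; return geometric-mean centers
    and the normalized density per bin (count / bin width / total)."""
    s_lo, s_hi = sizes.min(), sizes.max()
    n_dec = math.log10(s_hi / s_lo) if s_hi > s_lo else 0.0
    n_bins = max(1, int(math.ceil(n_dec * bins_per_decade)))
    edges = np.geomspace(s_lo, s_hi, n_bins + 1)
    edges[-1] *= 1.0 + 1e-12  # include the maximum
    counts, _ = np.histogram(sizes, bins=edges)
    widths = np.diff(edges)
    keep = counts > 0
    # geometric mean of the samples inside each bin (not the edge midpoint)
    idx = np.clip(np.searchsorted(edges, sizes, side="right") - 1, 0, n_bins - 1)
    logsum = np.bincount(idx, weights=np.log(sizes), minlength=n_bins)
    centers = np.exp(logsum[keep] / counts[keep])
    density = counts[keep] / widths[keep] / sizes.size
    return centers, density


def _ks_distance(sizes_in: np.ndarray, alpha: float, s_min: float, s_max: float) -> float:
    """KS distance between the in-range empirical CDF and the truncated
    continuous power-law CDF with exponent alpha."""
    s = np.sort(sizes_in.astype(float))
    n = s.size
    a1 = alpha + 1.0
    if abs(a1) < 1e-9:
        model = (np.log(s) - math.log(s_min)) / (math.log(s_max) - math.log(s_min))
    else:
        model = (s**a1 - s_min**a1) / (s_max**a1 - s_min**a1)
    emp_hi = np.arange(1, n + 1) / n
    emp_lo = np.arange(0, n) / n
    return float(max(np.max(np.abs(emp_hi - model)), np.max(np.abs(emp_lo - model))))


def fit_power_law(
    sizes: np.ndarray,
    bins_per_decade: int = 10,
    min_decade_span: float = 1.0,
    min_count: int = 50,
) -> PowerLawFit:
    """Fit P(s) ~ s^alpha by smoothing + KS-optimal range + log-log least squares.

    Candidate ranges are pairs of smoothed-bin centers spanning at least
    ``min_decade_span`` decades; each candidate's slope is the least-squares
    fit through the smoothed log-log points it contains, and its score is the
    KS distance between the raw in-range sizes and that power law.  The
    minimal-KS candidate wins.
    """
    sizes = np.asarray(sizes)
    sizes = sizes[sizes > 0]
    if sizes.size < 2 or np.unique(sizes).size < 2:
        raise ValueError("unfittable: need at least two distinct positive sizes")
    low_count = sizes.size < min_count
    if low_count:
        warnings.warn(
            f"power-law fit on only {sizes.size} avalanches (min_count={min_count})",
            stacklevel=2,
        )
    centers, density = _log_binned_density(sizes, bins_per_decade)
    logc, logd = np.log10(centers), np.log10(density)

    best = None
    m = centers.size
    for i in range(m - 1):
        for j in range(i + 1, m):
            if logc[j] - logc[i] < min_decade_span:
                continue
            cx, cy = logc[i : j + 1], logd[i : j + 1]
            if cx.size < 3:
                continue
            slope, _ = np.polyfit(cx, cy, 1)
            s_lo, s_hi = centers[i], centers[j]
            in_range = sizes[(sizes >= s_lo) & (sizes <= s_hi)]
            if in_range.size < 10:
                continue
            ks = _ks_distance(in_range, slope, s_lo, s_hi)
            if best is None or ks < best[0]:
                best = (ks, slope, s_lo, s_hi, in_range.size)
    if best is None:
        # data span under a decade: fall back to the full observed range
        if centers.size < 2:
            raise ValueError("unfittable: smoothed density has a single support point")
        slope, _ = np.polyfit(logc, logd, 1)
        ks = _ks_distance(sizes, slope, float(sizes.min()), float(sizes.max()))
        best = (ks, slope, float(sizes.min()), float(sizes.max()), sizes.size)
        low_count = True
    ks, alpha, s_lo, s_hi, n_in = best
    keep = (centers >= s_lo) & (centers <= s_hi)
    return PowerLawFit(
        alpha=float(alpha),
        s_min=float(s_lo),
        s_max=float(s_hi),
        ks=float(ks),
        n_in_range=int(n_in),
        centers=centers,
        density=density,
        low_count=low_count,
    )


def branching_parameter(
    avalanches: AvalancheSet, include_single_bin: bool = True
) -> BranchingEstimate:
    """sigma = mean over avalanches of (second-bin count)/(first-bin count).

    Single-bin avalanches have an empty second bin and contribute ratio 0 by
    default; set ``include_single_bin=False`` to drop them from the mean.
    """
    if avalanches.n_avalanches == 0:
        raise ValueError("empty avalanche set")
    anc, desc = avalanches.first_second_bins()
    n_single = int(np.sum(desc == 0))
    if not include_single_bin:
        keep = desc > 0
        if not np.any(keep):
            raise ValueError("no multi-bin avalanches to estimate sigma from")
        anc, desc = anc[keep], desc[keep]
    sigma = float(np.mean(desc / anc))
    return BranchingEstimate(sigma=sigma, ancestors=anc, descendants=desc, n_single_bin=n_single)
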