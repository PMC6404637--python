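"""Ground-truth generators for testing the analysis layer without the network.

Each generator produces data with a known parameter (offspring mean, power-law
exponent, correlation, ISI law) so that the estimators in
:mod:`pfcwm.criticality` and :mod:`pfcwm.balance` can be checked against the
truth.  None of the generators share numerical code with the estimators they
test.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "branching_raster",
    "powerlaw_sizes",
    "correlated_pair",
    "isi_train",
]


def branching_raster(
    offspring_mean: float,
    n_avalanches: int,
    seed: int,
    bin_ms: float = 0.3,
    gap_bins: int = 3,
    max_generations: int = 1000,
) -> np.ndarray:
    """Spike times (ms) from a Galton-Watson branching process.

    Each avalanche starts with a single active unit; every active unit in a
    generation produces Poisson(``offspring_mean``) active units in the next,
    one generation per ``bin_ms`` bin, until extinction.  Avalanches are
    separated by ``gap_bins`` empty bins.  Spikes are placed at bin centers so
    that re-binning at ``bin_ms`` recovers the generations exactly.

    ``max_generations`` truncates never-extinguishing (critical and
    supercritical) cascades; at criticality the unconditional mean avalanche
    size grows linearly with this cap, so memory scales as
    ``n_avalanches * max_generations``.
    """
    if offspring_mean < 0:
        raise ValueError("offspring mean must be >= 0")
    rng = np.random.default_rng(seed)
    times: list[np.ndarray] = []
    bin_cursor = 0
    for _ in range(n_avalanches):
        counts = [1]
        while counts[-1] > 0 and len(counts) < max_generations:
            counts.append(int(rng.poisson(offspring_mean * counts[-1])))
        counts = counts[:-1] if counts[-1] == 0 else counts
        for g, c in enumerate(counts):
            t = (bin_cursor + g + 0.5) * bin_ms
            times.append(np.full(c, t))
        bin_cursor += len(counts) + gap_bins
    return np.concatenate(times) if times else np.empty(0)


def powerlaw_sizes(
    alpha: float,
    s_range: tuple[int, int],
    n: int,
    seed: int,
) -> np.ndarray:
    """Discrete power-law sample P(s) ~ s^alpha on integer support ``s_range``.

    Inverse-CDF sampling from the exact normalized pmf; independent of the
    fitting code path.
    """
    if alpha >= -1:
        raise ValueError("alpha must be < -1 for a normalizable tail")
    s_lo, s_hi = s_range
    if not (1 <= s_lo < s_hi):
        raise ValueError("invalid size range")
    rng = np.random.default_rng(seed)
    support = np.arange(s_lo, s_hi + 1, dtype=np.float64)
    pmf = support**alpha
    cdf = np.cumsum(pmf)
    cdf /= cdf[-1]
    u = rng.random(n)
    return support[np.searchsorted(cdf, u)].astype(np.int64)


def correlated_pair(rho: float, n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Two standard-normal series with population correlation ``rho``."""
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    y = rho * x + math.sqrt(1.0 - rho * rho) * z
    return x, y


def isi_train(
    law: str,
    rate_hz: float,
    n: int,
    seed: int,
    shape: float = 4.0,
) -> np.ndarray:
    """Renewal-process spike train (times in ms) with a known ISI law.

    ``law``: ``periodic`` (CV=0), ``exponential`` (Poisson train, CV=1) or
    ``gamma`` (shape ``k``, CV=1/sqrt(k)); ``rate_hz`` fixes the mean ISI.
    """
    if rate_hz <= 0 or n < 1:
        raise ValueError("need positive rate and at least one interval")
    mean_isi = 1000.0 / rate_hz
    rng = np.random.default_rng(seed)
    if law == "periodic":
        isis = np.full(n, mean_isi)
    elif law == "exponential":
        isis = rng.exponential(mean_isi, size=n)
    elif law == "gamma":
        if shape <= 0:
            raise ValueError("gamma shape must be positive")
        isis = rng.gamma(shape, mean_isi / shape, size=n)
    else:
        raise ValueError(f"unknown ISI law {law!r}")
    return np.cumsum(isis)
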