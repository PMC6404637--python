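"""Avalanche detection, exponent fitting, branching parameter — against
ground-truth generators that share no code with the estimators."""

import numpy as np
import pytest

from pfcwm import branching_parameter, detect_avalanches, fit_power_law
from pfcwm.criticality import adaptive_bin_width
from pfcwm.fixtures import branching_raster, powerlaw_sizes


def raster_from_bin_counts(counts, bin_ms=1.0):
    """Spike times realizing the given per-bin counts (at bin centers)."""
    times = []
    for k, c in enumerate(counts):
        times.extend([(k + 0.5) * bin_ms] * int(c))
    return np.asarray(times)


class TestDetection:
    def test_two_avalanches_from_count_pattern(self):
        """The canonical picture: counts [0,2,3,1,0,3,0] -> sizes 6 and 3."""
        t = raster_from_bin_counts([0, 2, 3, 1, 0, 3, 0])
        av = detect_avalanches(t, 1.0, t0=0.0)
        assert av.n_avalanches == 2
        assert list(av.sizes) == [6, 3]
        assert list(av.durations) == [3, 1]

    def test_empty_raster(self):
        av = detect_avalanches(np.array([]), 0.3)
        assert av.n_avalanches == 0
        assert av.total_spikes == 0

    def test_single_bin_all_spikes(self):
        t = np.full(17, 0.05)
        av = detect_avalanches(t, 0.3)
        assert av.n_avalanches == 1
        assert av.sizes[0] == 17

    def test_size_conservation(self):
        """Sum of avalanche sizes equals the raster's total spike count."""
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(0, 500, size=2000))
        av = detect_avalanches(t, 0.3, t0=0.0)
        assert av.total_spikes == 2000
        assert av.sizes.sum() == 2000

    def test_global_time_shift_invariance(self):
        """Shifting all spikes by a multiple of the bin width leaves the
        avalanche decomposition unchanged."""
        rng = np.random.default_rng(6)
        t = np.sort(rng.uniform(0, 200, size=500))
        a = detect_avalanches(t, 0.5, t0=0.0)
        b = detect_avalanches(t + 5 * 0.5, 0.5, t0=0.0)
        assert list(a.sizes) == list(b.sizes)
        assert np.array_equal(a.bin_counts, b.bin_counts)

    def test_adaptive_bin_width_is_twice_mean_iei(self):
        t = np.array([0.0, 1.0, 3.0, 6.0])  # IEIs 1,2,3 -> mean 2
        assert adaptive_bin_width(t) == pytest.approx(4.0)


class TestBranching:
    def test_direct_ratio(self):
        av = detect_avalanches(raster_from_bin_counts([0, 1, 3, 2, 0]), 1.0, t0=0.0)
        assert branching_parameter(av).sigma == pytest.approx(3.0)

    def test_single_bin_contributes_zero(self):
        av = detect_avalanches(raster_from_bin_counts([2, 4, 0, 1, 0]), 1.0, t0=0.0)
        est = branching_parameter(av)
        assert est.sigma == pytest.approx((4 / 2 + 0) / 2)
        assert est.n_single_bin == 1
        # exclusion switch drops the single-bin avalanche
        assert branching_parameter(av, include_single_bin=False).sigma == pytest.approx(2.0)

    def test_empty_set_rejected(self):
        av = detect_avalanches(np.array([]), 0.3)
        with pytest.raises(ValueError):
            branching_parameter(av)

    @pytest.mark.parametrize("m", [0.0, 0.5, 0.8, 1.0])
    def test_recovers_offspring_mean(self, m):
        """Galton-Watson rasters: the estimator recovers the offspring mean
        (ancestor count is 1, so the ratio estimator is unbiased)."""
        t = branching_raster(m, n_avalanches=10_000, seed=11, bin_ms=0.3)
        av = detect_avalanches(t, 0.3, t0=0.0)
        est = branching_parameter(av)
        if m == 0.0:
            assert est.sigma == 0.0
            assert est.n_single_bin == av.n_avalanches
        else:
            assert est.sigma == pytest.approx(m, abs=0.05)

    def test_critical_tail_heavier_than_subcritical(self):
        """Offspring mean 1.0 stochastically dominates 0.8 in the upper size
        quantiles."""
        t_sub = branching_raster(0.8, 10_000, seed=3)
        t_crit = branching_raster(1.0, 10_000, seed=3)
        s_sub = detect_avalanches(t_sub, 0.3, t0=0.0).sizes
        s_crit = detect_avalanches(t_crit, 0.3, t0=0.0).sizes
        for q in (0.9, 0.99, 0.999):
            assert np.quantile(s_crit, q) >= np.quantile(s_sub, q)


class TestPowerLawFit:
    def test_recovers_known_exponent(self):
        sizes = powerlaw_sizes(-1.5, (1, 10_000), 10_000, seed=21)
        fit = fit_power_law(sizes)
        assert -1.6 <= fit.alpha <= -1.4
        assert not fit.low_count

    def test_exponent_ordering_preserved(self):
        s_steep = powerlaw_sizes(-3.0, (1, 10_000), 10_000, seed=22)
        s_shallow = powerlaw_sizes(-1.5, (1, 10_000), 10_000, seed=22)
        assert fit_power_law(s_steep).alpha < fit_power_law(s_shallow).alpha

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="unfittable"):
            fit_power_law(np.full(100, 7))

    def test_low_count_flagged(self):
        sizes = powerlaw_sizes(-1.5, (1, 100), 10, seed=23)
        with pytest.warns(UserWarning, match="only"):
            fit = fit_power_law(sizes)
        assert fit.low_count

    def test_exponential_tail_fits_worse_than_power_law(self):
        """KS distance of the best power-law fit is larger for geometric
        (exponential-tailed) sizes than for a true power-law sample."""
        rng = np.random.default_rng(24)
        geo = rng.geometric(1 / 3, size=10_000)
        pl = powerlaw_sizes(-1.5, (1, 10_000), 10_000, seed=25)
        assert fit_power_law(geo).ks > fit_power_law(pl).ks

    def test_fit_range_within_observed_sizes(self):
        sizes = powerlaw_sizes(-2.0, (1, 5000), 5000, seed=26)
        fit = fit_power_law(sizes)
        assert sizes.min() <= fit.s_min < fit.s_max <= sizes.max()
        assert 0 <= fit.ks <= 1
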