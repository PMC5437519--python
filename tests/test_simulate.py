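"""Point-process simulators: calibration, distribution shape, determinism."""

import numpy as np
import pytest
from scipy import stats

from rainplot import (
    HmpModel,
    NhppProfile,
    distance_histogram,
    simulate_hmp,
    simulate_hpp,
    simulate_nhpp,
)
from rainplot.simulate import _hpp_arrivals


class TestHpp:
    def test_same_seed_same_output(self):
        a = simulate_hpp(0.01, 1_000_000, seed=7)
        b = simulate_hpp(0.01, 1_000_000, seed=7)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, simulate_hpp(0.01, 1_000_000, seed=8))

    def test_positions_strictly_increasing_in_bounds(self):
        p = simulate_hpp(0.1, 50_000, seed=1)
        assert np.all(np.diff(p) > 0)
        assert p[0] >= 0 and p[-1] < 50_000

    def test_mean_count_matches_lambda_t_over_replicates(self):
        """E[N(t)] = lambda * t within 4 standard errors over 200 replicates."""
        lam, length, reps = 0.001, 1_000_000, 200
        counts = np.array([len(simulate_hpp(lam, length, seed=s)) for s in range(reps)])
        expected = lam * length
        se = np.sqrt(expected / reps)
        assert abs(counts.mean() - expected) < 4 * se

    def test_inter_arrivals_exponential(self):
        """Pre-rounding gaps pass a KS test against Exp(mean 1/lambda)."""
        rng = np.random.default_rng(123)
        arrivals = _hpp_arrivals(rng, 0.01, 1_200_000)
        gaps = np.diff(arrivals[:10_001])
        assert len(gaps) == 10_000
        res = stats.kstest(gaps, "expon", args=(0, 100.0))
        assert res.pvalue > 0.01

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_rejects_non_positive_intensity(self, bad):
        with pytest.raises(ValueError):
            simulate_hpp(bad, 1000, seed=0)


class TestNhpp:
    PROFILE = NhppProfile(
        segments=(
            (100_000, 200_000, 0.001),
            (300_000, 310_000, 0.001),
            (500_000, 600_000, 0.01),
            (700_000, 710_000, 0.01),
        ),
        region_length=1_000_000,
    )

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            NhppProfile(((0, 100, 0.01), (50, 150, 0.01)), 1000)

    def test_segment_outside_region_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            NhppProfile(((500, 1500, 0.01),), 1000)

    def test_mean_distance_parameterization(self):
        prof = NhppProfile.from_mean_distances(((0, 100, 50.0),), 1000)
        assert prof.segments[0][2] == pytest.approx(0.02)

    def test_per_segment_counts_match_intensity_times_extent(self):
        """Mean per-segment count over replicates is lambda * extent."""
        reps = 30
        per_seg = np.zeros(len(self.PROFILE.segments))
        for s in range(reps):
            pos = simulate_nhpp(self.PROFILE, baseline=1e-5, seed=s)
            for i, (a, b, _) in enumerate(self.PROFILE.segments):
                per_seg[i] += ((pos >= a) & (pos < b)).sum()
        per_seg /= reps
        for (a, b, lam), got in zip(self.PROFILE.segments, per_seg):
            expected = lam * (b - a)
            se = np.sqrt(expected / reps)
            assert abs(got - expected) < 5 * se

    def test_segment_gaps_indistinguishable_from_hpp(self):
        """Distances inside a hotspot segment match an HPP at that lambda."""
        prof = NhppProfile(((0, 2_000_000, 0.01),), 2_000_000)
        a = simulate_nhpp(prof, baseline=0.0, seed=42)
        b = simulate_hpp(0.01, 2_000_000, seed=43)
        res = stats.ks_2samp(np.diff(a), np.diff(b))
        assert res.pvalue > 0.01

    def test_empty_segment_list_reduces_to_baseline_hpp(self):
        prof = NhppProfile((), 1_000_000)
        a = simulate_nhpp(prof, baseline=0.005, seed=9)
        b = simulate_hpp(0.005, 1_000_000, seed=10)
        assert abs(len(a) - len(b)) < 5 * np.sqrt(5000)
        res = stats.ks_2samp(np.diff(a), np.diff(b))
        assert res.pvalue > 0.01

    def test_zero_baseline_confines_events_to_segments(self):
        pos = simulate_nhpp(self.PROFILE, baseline=0.0, seed=3)
        in_any = np.zeros(len(pos), dtype=bool)
        for a, b, _ in self.PROFILE.segments:
            in_any |= (pos >= a) & (pos < b)
        assert in_any.all()


class TestHmp:
    def test_model_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            HmpModel((0.01, 0.001), ((0.5, 0.4), (0.5, 0.5)))
        with pytest.raises(ValueError, match="positive"):
            HmpModel((0.0,), ((1.0,),))

    def test_stationary_distribution_of_equal_rows(self):
        model = HmpModel.two_state(hot_probability=0.8)
        assert np.allclose(model.stationary_distribution(), [0.8, 0.2])

    def test_same_seed_same_realization(self):
        model = HmpModel.two_state()
        a = simulate_hmp(model, 1_000_000, seed=5)
        b = simulate_hmp(model, 1_000_000, seed=5)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.states, b.states)

    def test_state_fraction_matches_stationary_probability(self):
        model = HmpModel.two_state(hot_probability=0.8)
        real = simulate_hmp(model, 20_000_000, seed=2)
        frac_hot = (real.states == 0).mean()
        n = len(real.states)
        assert abs(frac_hot - 0.8) < 4 * np.sqrt(0.8 * 0.2 / n) + 0.01

    def test_single_state_model_is_an_hpp(self):
        model = HmpModel((0.01,), ((1.0,),))
        real = simulate_hmp(model, 2_000_000, seed=21)
        ref = simulate_hpp(0.01, 2_000_000, seed=22)
        res = stats.ks_2samp(np.diff(real.positions), np.diff(ref))
        assert res.pvalue > 0.01

    def test_parameter_recovery_from_true_states(self):
        """1 / mean(gap | generating state) recovers each lambda within 10%."""
        model = HmpModel.two_state()
        real = simulate_hmp(model, 25_000_000, seed=17)
        assert len(real.positions) > 10_000
        gaps = np.diff(real.positions)
        gap_states = real.states[1:]  # gap i was drawn at the state of event i+1
        for k, lam in enumerate(model.intensities):
            est = 1.0 / gaps[gap_states == k].mean()
            assert abs(est - lam) / lam < 0.10

    def test_two_state_distance_histogram_is_bimodal(self):
        model = HmpModel.two_state()
        real = simulate_hmp(model, 20_000_000, seed=1)
        hist = distance_histogram(real.positions, bins=40)
        peaks = _top_two_separated_peaks(hist.counts, hist.centers)
        assert sorted(round(p) for p in peaks) == [2, 4]


def _top_two_separated_peaks(counts, centers, min_sep=1.5):
    """Locations of the two highest histogram peaks at distinct scales.

    The second peak is the highest bin at least ``min_sep`` log-units from
    the first; the states' scales sit two decades apart, so 1.5 decades
    separates the modes while excluding each mode's own flank."""
    order = np.argsort(counts)[::-1]
    first = centers[order[0]]
    for i in order[1:]:
        if abs(centers[i] - first) >= min_sep:
            return first, centers[i]
    raise AssertionError("no second peak")


class TestDistanceHistogram:
    def test_arithmetic_sequence_occupies_a_single_bin(self):
        hist = distance_histogram(np.arange(0, 5000, 50), bins=20)
        assert (hist.counts > 0).sum() == 1
        occupied = hist.centers[np.argmax(hist.counts)]
        assert abs(occupied - np.log10(50)) < (hist.edges[1] - hist.edges[0])

    def test_fewer_than_two_positions_empty(self):
        assert len(distance_histogram([5]).counts) == 0
        assert len(distance_histogram([]).counts) == 0

    def test_hpp_histogram_unimodal_with_mode_at_mean_distance(self):
        """Exponential gaps on a log axis peak near log10(1/lambda), and the
        distribution is far from uniform across decades."""
        pos = simulate_hpp(0.01, 10_000_000, seed=6)
        hist = distance_histogram(pos, bins=40)
        peak = int(np.argmax(hist.counts))
        mode = hist.centers[peak]
        assert abs(mode - 2.0) < 0.25
        # density falls away sharply on both flanks of the single mode
        left = hist.counts[np.argmin(np.abs(hist.centers - (mode - 1.5)))]
        right = hist.counts[np.argmin(np.abs(hist.centers - (mode + 1.0)))]
        assert hist.counts[peak] > 5 * left
        assert hist.counts[peak] > 5 * right
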