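"""Error cutoff, windowed local maxima, homozygous peak and valley calling."""

import numpy as np
import pytest
from hypothesis import assume, given, strategies as st

from gset.histio import KmerHistogram
from gset.peakcall import (
    call_peaks,
    curve_area,
    error_cutoff,
    find_valley,
    homozygous_peak,
    local_maxima,
    smooth_counts,
    total_instances,
)
from gset.synth import TruthRecord, simulate_histogram

from conftest import brute_local_maxima


def H(entries, k=None):
    return KmerHistogram(entries=tuple(entries), k=k)


histograms = st.dictionaries(
    st.integers(1, 60), st.integers(0, 1000), min_size=2, max_size=40,
).map(lambda d: H(sorted(d.items())))


class TestAreas:
    def test_totals(self):
        h = H([(1, 100), (2, 50), (30, 500)])
        assert total_instances(h) == 15200
        assert curve_area(h) == 650
        assert curve_area(H([(5, 7)])) == 7

    def test_zero_content(self):
        assert total_instances(H([(1, 0), (2, 0)])) == 0


class TestErrorCutoff:
    def test_zero_error_rate_means_zero_cutoff(self):
        assert error_cutoff(H([(1, 5), (9, 9)]), 0.0).L == 0

    def test_hand_accumulation(self):
        h = H([(1, 90), (2, 5), (30, 5)])
        r = error_cutoff(h, 0.9)
        assert (r.S, r.S_prime, r.L) == (100.0, 90.0, 1)
        assert error_cutoff(h, 0.92).L == 2

    def test_instance_weighted_basis(self):
        h = H([(1, 90), (2, 5), (30, 5)])
        # S = 90 + 10 + 150 = 250; S' = 100 reached at x=2 (cum 90, 100)
        r = error_cutoff(h, 0.4, area_basis="instances")
        assert (r.S, r.L) == (250.0, 2)

    def test_parameter_and_consistency_errors(self):
        h = H([(1, 90), (2, 5), (30, 5)])
        for bad in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                error_cutoff(h, bad)
        with pytest.raises(ValueError, match="inconsistent"):
            error_cutoff(h, 0.99)  # share swallows the whole spectrum

    @given(histograms, st.floats(0, 0.5), st.floats(0, 0.5))
    def test_monotone_in_error_rate(self, h, e1, e2):
        e1, e2 = min(e1, e2), max(e1, e2)
        try:
            L2 = error_cutoff(h, e2).L
        except ValueError:
            assume(False)
        assert error_cutoff(h, e1).L <= L2


class TestLocalMaxima:
    def test_degenerate_shapes(self):
        assert local_maxima(H([(5, 7)]), 0) == [(5, 7)]
        decreasing = H([(1, 50), (2, 40), (3, 30), (4, 20)])
        assert local_maxima(decreasing, 1) == [(1, 50)]

    def test_windowed_example(self):
        h = H([(1, 1000), (2, 100), (3, 20), (28, 300), (30, 500), (32, 400)])
        assert local_maxima(h, 3) == [(1, 1000), (30, 500)]
        assert local_maxima(h, 3) == brute_local_maxima(h.entries, 3)

    def test_plateau_reports_leftmost(self):
        h = H([(10, 5), (11, 5), (12, 3)])
        assert local_maxima(h, 1) == [(10, 5)]

    @given(histograms, st.integers(0, 10))
    def test_matches_window_scan_oracle(self, h, L):
        assert local_maxima(h, L) == brute_local_maxima(h.entries, L)

    def test_thousand_random_histograms_vs_oracle(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 25))
            xs = np.sort(rng.choice(np.arange(1, 80), size=n, replace=False))
            ys = rng.integers(0, 50, size=n)
            h = H(list(zip(xs.tolist(), ys.tolist())))
            L = int(rng.integers(0, 8))
            assert local_maxima(h, L) == brute_local_maxima(h.entries, L)


class TestHomozygousPeak:
    def test_selection_and_ties(self):
        assert homozygous_peak([(1, 1000), (30, 500)], 3) == (30, 500)
        assert homozygous_peak([(20, 400), (40, 400)], 3) == (20, 400)

    def test_nothing_right_of_cutoff(self):
        with pytest.raises(ValueError, match="no homozygous peak"):
            homozygous_peak([(1, 1000)], 3)
        with pytest.raises(ValueError):
            homozygous_peak([], 3)


class TestFindValley:
    def test_construction(self):
        h = H([(1, 1000), (5, 10), (30, 500)])
        assert find_valley(h, 0, 30) == (5, 10)

    def test_monotone_limb_takes_edge_minimum(self):
        h = H([(1, 5), (2, 10), (30, 500)])
        assert find_valley(h, 0, 30) == (1, 5)

    def test_empty_range_defaults_to_cutoff_edge(self):
        h = H([(2, 7), (30, 500)])
        assert find_valley(h, 4, 30) == (4, 0)

    def test_matches_argmin_scan(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 20))
            xs = np.sort(rng.choice(np.arange(1, 50), size=n, replace=False))
            ys = rng.integers(0, 100, size=n)
            h = H(list(zip(xs.tolist(), ys.tolist())))
            xm = int(xs[-1])
            got = find_valley(h, 0, xm)
            in_range = [(x, y) for x, y in h.entries if 1 <= x < xm]
            expect = min(in_range, key=lambda p: (p[1], p[0]))
            assert got == expect

    def test_valley_left_of_peak_required(self):
        with pytest.raises(ValueError):
            find_valley(H([(5, 1)]), 5, 5)
        with pytest.raises(ValueError, match="not present"):
            find_valley(H([(5, 1)]), 0, 7)


class TestSmoothing:
    def test_width_three_truncated_mean(self):
        h = H([(1, 3), (2, 6), (3, 9)])
        assert smooth_counts(h).entries == ((1, 4), (2, 6), (3, 8))
        with pytest.raises(ValueError):
            smooth_counts(h, width=2)


class TestCallPeaks:
    def test_clean_spectrum_end_to_end(self):
        truth = TruthRecord(true_genome_size=100_000, coverage=30,
                            error_instance_weight=0.10, mode="expected")
        h = simulate_histogram(truth)
        call = call_peaks(h, error_rate=0.02)
        assert call.xm in (29, 30)  # Poisson(30) is bimodal at {29, 30}
        assert call.L < call.xv <= call.xm
        assert call.peak in call.maxima

    def test_no_error_limb_zero_rate(self):
        truth = TruthRecord(true_genome_size=50_000, coverage=30.5,
                            mode="expected")
        h = simulate_histogram(truth)
        call = call_peaks(h, error_rate=0.0)
        assert call.L == 0
        assert call.xm == int(h.x[np.argmax(h.y)]) == 30

    def test_het_mode_selects_homozygous_peak(self):
        # heterozygous k-mers at half coverage outnumber the homozygous peak
        truth = TruthRecord(true_genome_size=200_000, coverage=30.5,
                            het_weight=0.55, mode="expected")
        h = simulate_histogram(truth)
        assert h.y_at(15) > h.y_at(30)
        naive = call_peaks(h, error_rate=0.01, het_mode=False)
        assert naive.xm == 15
        het = call_peaks(h, error_rate=0.01, het_mode=True)
        assert het.xm == 30
        assert het.het_rule_fired

    def test_peak_always_right_of_cutoff(self, rng):
        for seed in range(10):
            truth = TruthRecord(true_genome_size=20_000,
                                coverage=float(rng.integers(8, 60)),
                                error_instance_weight=float(rng.uniform(0, 0.3)),
                                seed=seed, mode="sampled")
            h = simulate_histogram(truth)
            call = call_peaks(h, error_rate=0.01)
            assert call.xm > call.L
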