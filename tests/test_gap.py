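"""Gap analysis: binning, smoothing, extremum detection, valley
validation, bootstrap consensus, and the four-group classifier."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import anigap as ag
from anigap.gap import PeakParams, SmootherSpec


def make_table(anis, species="sp"):
    """Wrap a list of ANI values into a labeled one-species AniTable."""
    pairs = []
    labels = {}
    for i, v in enumerate(anis):
        q, s = f"g{2 * i}", f"g{2 * i + 1}"
        pairs.append(ag.AniPair(query_id=q, subject_id=s, ani=float(v),
                                fragments_mapped=10, fragments_total=10))
        labels[q] = species
        labels[s] = species
    return ag.AniTable(pairs=pairs), labels


class TestUniformExpectation:
    def test_headline_arithmetic(self):
        # 43,200 pairs over 51 bins -> ~847 per bin
        assert ag.uniform_expectation(43200, 51) == pytest.approx(847.06, abs=0.01)
        assert round(ag.uniform_expectation(43200, 51)) == 847

    @pytest.mark.parametrize("total,bins,expected", [(0, 51, 0.0), (51, 51, 1.0)])
    def test_edge_values(self, total, bins, expected):
        assert ag.uniform_expectation(total, bins) == expected


class TestBuildHistogram:
    def test_nearest_center_rule(self):
        h = ag.build_histogram([95.0, 95.04, 95.06])
        assert h.counts[0] == 2 and h.counts[1] == 1
        assert h.counts.sum() == 3

    def test_empty_input(self):
        h = ag.build_histogram([])
        assert len(h.bin_centers) == 51
        assert h.counts.sum() == 0

    def test_uniform_values_near_expectation(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(94.95, 100.05, size=43200)
        h = ag.build_histogram(vals)
        assert h.counts.sum() == 43200
        sd = np.sqrt(43200 * (1 / 51) * (50 / 51))
        assert np.all(np.abs(h.counts - 847.06) < 4 * sd)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="94.2"):
            ag.build_histogram([97.0, 94.2])

    @given(st.lists(st.floats(min_value=94.96, max_value=100.04), max_size=200))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_count_conservation(self, vals):
        assert ag.build_histogram(vals).counts.sum() == len(vals)


class TestSmoothCounts:
    def test_constant_series_preserved(self):
        h = ag.build_histogram([])
        h.counts[:] = 10
        for spec in (SmootherSpec(), SmootherSpec(method="moving_average", window=3)):
            hs = ag.smooth_counts(h, spec)
            assert np.allclose(hs.smoothed, 10.0)

    def test_spike_spreads_but_keeps_location(self):
        h = ag.build_histogram([])
        h.counts[25] = 100
        hs = ag.smooth_counts(h)
        assert hs.smoothed.argmax() == 25
        assert hs.smoothed[25] < 100
        assert hs.smoothed[24] > 0 and hs.smoothed[26] > 0

    def test_moving_average_hand_computed(self):
        # reflect padding of [0,9,0] -> [9,0,9,0,9]; middle window mean = 3
        h = ag.AniHistogram(bin_centers=np.arange(5.0), counts=np.array([1, 0, 9, 0, 1]))
        hs = ag.smooth_counts(h, SmootherSpec(method="moving_average", window=3))
        assert hs.smoothed[2] == pytest.approx(3.0)

    def test_mass_roughly_conserved(self):
        rng = np.random.default_rng(0)
        h = ag.build_histogram(rng.uniform(95.0, 100.0, 2000))
        hs = ag.smooth_counts(h)
        assert hs.smoothed.sum() == pytest.approx(h.counts.sum(), rel=0.10)

    def test_too_few_bins_rejected(self):
        h = ag.AniHistogram(bin_centers=np.arange(3.0), counts=np.zeros(3, dtype=int))
        with pytest.raises(ValueError, match="5 bins"):
            ag.smooth_counts(h)


class TestDetectAndValidate:
    def _hist(self, smoothed):
        s = np.asarray(smoothed, dtype=float)
        return ag.AniHistogram(bin_centers=np.arange(len(s), dtype=float),
                               counts=np.zeros(len(s), dtype=int), smoothed=s)

    def test_single_peak(self):
        pv = ag.detect_peaks_valleys(self._hist([1, 5, 1]))
        assert pv.peaks() == [1.0]
        assert pv.valleys() == []

    def test_single_valley(self):
        pv = ag.detect_peaks_valleys(self._hist([5, 1, 5]))
        assert pv.valleys() == [1.0]

    def test_bimodal_oracle(self):
        """Two well-separated normal humps: detection must agree with a
        brute-force local-extremum scan."""
        from scipy.stats import norm
        x = 95 + 0.1 * np.arange(51)
        s = 200 * norm.pdf((x - 97) / 0.4) + 200 * norm.pdf((x - 99.9) / 0.1)
        hist = self._hist(s)
        hist.bin_centers = x
        pv = ag.detect_peaks_valleys(hist)
        # oracle: interior strict local extrema
        peaks = [x[i] for i in range(1, 50) if s[i] > s[i - 1] and s[i] > s[i + 1]]
        assert pv.peaks() == pytest.approx(peaks)
        assert len(pv.valleys()) == 1
        assert peaks[0] < pv.valleys()[0] < peaks[1]

    def test_validation_rule(self):
        hist = self._hist([10, 10, 2, 10, 10])
        pv = ag.detect_peaks_valleys(hist)
        assert ag.validate_valleys(hist, pv) == [2.0]
        hist2 = self._hist([10, 10, 9, 10, 10])
        pv2 = ag.detect_peaks_valleys(hist2)
        assert ag.validate_valleys(hist2, pv2) == []

    def test_no_candidates(self):
        hist = self._hist([1, 2, 3, 4, 5])
        pv = ag.detect_peaks_valleys(hist)
        assert ag.validate_valleys(hist, pv) == []


class TestSubsample:
    def test_exact_counts_and_exclusion(self):
        rng = np.random.default_rng(3)
        t1, l1 = make_table(rng.uniform(98, 100, 200), "sp1")
        t2, l2 = make_table(rng.uniform(98, 100, 100), "sp2")
        # merge, relabeling genome ids to avoid collisions
        pairs = t1.pairs + [
            ag.AniPair(query_id="x" + p.query_id, subject_id="x" + p.subject_id,
                       ani=p.ani, fragments_mapped=10, fragments_total=10)
            for p in t2.pairs
        ]
        labels = dict(l1)
        labels.update({"x" + k: "sp2" for k in l2})
        table = ag.AniTable(pairs=pairs)
        sub = ag.subsample_pairs(table, labels, per_species=150, seed=1)
        assert len(sub) == 150  # sp2 (100 pairs) excluded entirely

    def test_determinism(self):
        t, labels = make_table(np.linspace(96, 100, 300))
        a = ag.subsample_pairs(t, labels, 150, seed=9)
        b = ag.subsample_pairs(t, labels, 150, seed=9)
        assert [(p.query_id, p.ani) for p in a.pairs] == [
            (p.query_id, p.ani) for p in b.pairs
        ]

    def test_no_qualifying_species(self):
        t, labels = make_table([99.0, 99.1])
        with pytest.raises(ValueError, match="at least"):
            ag.subsample_pairs(t, labels, 150, seed=0)


class TestBootstrap:
    def _bimodal_table(self, seed=4):
        rng = np.random.default_rng(seed)
        vals = np.concatenate([
            np.clip(rng.normal(98.8, 0.08, 300), 95, 100),
            np.clip(rng.normal(99.92, 0.04, 300), 95, 100),
        ])
        return make_table(vals)

    def test_single_rep_frequencies_binary(self):
        t, labels = self._bimodal_table()
        b = ag.bootstrap_gap(t, labels, reps=1, per_species=150, seed=2)
        assert set(np.unique(b.peak_freq)) <= {0.0, 1.0}
        assert set(np.unique(b.valley_freq)) <= {0.0, 1.0}

    def test_determinism(self):
        t, labels = self._bimodal_table()
        b1 = ag.bootstrap_gap(t, labels, reps=20, per_species=150, seed=5)
        b2 = ag.bootstrap_gap(t, labels, reps=20, per_species=150, seed=5)
        assert np.array_equal(b1.valley_freq, b2.valley_freq)
        assert b1.deepest_consistent_valley == b2.deepest_consistent_valley

    def test_planted_valley_found_in_gap(self):
        t, labels = self._bimodal_table()
        b = ag.bootstrap_gap(t, labels, reps=50, per_species=150, seed=6)
        in_gap = (b.bin_centers >= 99.2) & (b.bin_centers <= 99.8)
        assert b.valley_freq[in_gap].sum() >= 0.95
        assert 99.2 <= b.deepest_consistent_valley <= 99.8


class TestClassifySpecies:
    def test_clonal_group2(self):
        rng = np.random.default_rng(8)
        res = ag.classify_species(rng.uniform(99.9, 100.0, 200))
        assert res.group == 2

    def test_bimodal_group1(self):
        rng = np.random.default_rng(9)
        vals = np.concatenate([
            np.clip(rng.normal(98.8, 0.08, 200), 95, 100),
            np.clip(rng.normal(99.92, 0.04, 200), 95, 100),
        ])
        res = ag.classify_species(vals)
        assert res.group == 1
        assert res.validated_valleys_in_gap

    def test_peak_in_gap_group4(self):
        rng = np.random.default_rng(10)
        vals = np.concatenate([
            np.clip(rng.normal(99.5, 0.1, 300), 95, 100),
            np.clip(rng.normal(97.0, 0.3, 120), 95, 100),
        ])
        res = ag.classify_species(vals)
        assert res.group == 4

    def test_undetermined_group3(self):
        rng = np.random.default_rng(11)
        res = ag.classify_species(np.clip(rng.normal(97.5, 0.4, 300), 95, 100))
        assert res.group == 3

    def test_long_read_preset(self):
        rng = np.random.default_rng(12)
        vals = np.clip(rng.normal(99.6, 0.05, 200), 95, 100)
        res = ag.classify_species(
            vals, gap_range=(98.8, 99.5), clonal_threshold=99.5
        )
        assert res.group == 2  # mean > 99.5 under the long-read preset

    def test_too_few_values(self):
        with pytest.raises(ValueError, match="at least 2"):
            ag.classify_species([99.0])

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_every_distribution_lands_in_one_group(self, seed):
        """Random mixtures always land in exactly one of the four groups,
        following the fixed precedence."""
        rng = np.random.default_rng(seed)
        k = rng.integers(1, 4)
        vals = np.concatenate([
            np.clip(rng.normal(rng.uniform(95.5, 100.0), rng.uniform(0.03, 0.5),
                               rng.integers(20, 200)), 95, 100)
            for _ in range(k)
        ])
        res = ag.classify_species(vals)
        assert res.group in (1, 2, 3, 4)
        if res.group == 2:
            assert res.mean_ani > 99.8
        if res.group == 1:
            assert res.validated_valleys_in_gap
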