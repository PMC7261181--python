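"""Quartile classification, heatmaps, domain scaling, and enrichment statistic."""

import numpy as np
import pytest

from rerepseq.genome_io import BinnedTrack, IntervalSet
from rerepseq.timing_domains import (
    DegenerateProfileError,
    RankedDomainList,
    TimingError,
    classify_timing_regions,
    enrichment_score,
    extend_domains_to_tz_midpoints,
    feature_heatmap,
    rank_domains,
    scaled_domain_profile,
)


def track_of(vals, bw=100, chrom="c"):
    return BinnedTrack(bw, {chrom: np.asarray(vals, dtype=float)})


class TestClassify:
    def test_eight_bin_percentile_oracle(self):
        vals = [2.0, 2.0, 1.9, 1.5, 1.4, 1.2, 1.0, 1.0]
        q75, q25 = np.percentile(vals, 75), np.percentile(vals, 25)
        out = classify_timing_regions(track_of(vals))
        early = out.with_label("early").records
        late = out.with_label("late").records
        exp_early_bins = [i for i, v in enumerate(vals) if v >= q75]
        exp_late_bins = [i for i, v in enumerate(vals) if v <= q25]
        got_early = [b for c, s, e, *_ in early for b in range(s // 100, e // 100)]
        got_late = [b for c, s, e, *_ in late for b in range(s // 100, e // 100)]
        assert got_early == exp_early_bins
        assert got_late == exp_late_bins

    def test_alternating_singleton_runs(self):
        vals = [2.0, 1.0] * 4
        out = classify_timing_regions(track_of(vals))
        for c, s, e, lab, _ in out:
            assert e - s == 100  # every run is one bin

    def test_monotone_ramp_quartile_counts(self):
        vals = np.linspace(1.0, 2.0, 8)
        out = classify_timing_regions(track_of(vals))
        early = out.with_label("early").records
        late = out.with_label("late").records
        assert early == [("c", 600, 800, "early", None)]
        assert late == [("c", 0, 200, "late", None)]

    def test_degenerate_profile_error(self):
        with pytest.raises(DegenerateProfileError):
            classify_timing_regions(track_of([1.0] * 8))

    def test_early_late_disjoint(self, rng):
        vals = rng.uniform(1, 2, size=100)
        out = classify_timing_regions(track_of(vals))
        early_bins = {b for c, s, e, *_ in out.with_label("early") for b in range(s // 100, e // 100)}
        late_bins = {b for c, s, e, *_ in out.with_label("late") for b in range(s // 100, e // 100)}
        assert not early_bins & late_bins
        assert len(early_bins) + len(late_bins) >= 2 * (100 // 4)


class TestFeatureHeatmap:
    def test_constant_track_single_row(self):
        t = track_of([3.0] * 100)
        mat, ids = feature_heatmap(t, IntervalSet([("c", 4000, 6000, "f", None)]), 2000)
        assert mat.shape == (1, 40)
        np.testing.assert_allclose(mat[0], 3.0)

    def test_rows_sorted_by_sum_descending(self):
        vals = np.zeros(100)
        vals[10:20] = 1.0  # around feature a
        vals[60:70] = 2.0  # around feature b
        t = track_of(vals)
        centers = IntervalSet([("c", 1400, 1600, "a", None), ("c", 6400, 6600, "b", None)])
        _mat, ids = feature_heatmap(t, centers, 1000)
        assert ids == ["b@c:6400-6600", "a@c:1400-1600"]

    def test_edge_feature_nan_padded(self):
        t = track_of([1.0] * 100)
        mat, _ = feature_heatmap(t, IntervalSet([("c", 400, 600, "f", None)]), 2500)
        # midpoint 500, window [-2000, 3000): left 20 bins out of range
        assert np.isnan(mat[0][:20]).all()
        assert np.isfinite(mat[0][20:]).all()

    def test_empty_centers_error(self):
        with pytest.raises(TimingError):
            feature_heatmap(track_of([1.0]), IntervalSet([]), 1000)

    def test_row_order_invariant_to_rescaling(self, rng):
        vals = rng.uniform(size=200)
        centers = IntervalSet(
            [("c", int(p), int(p) + 200, f"f{i}", None) for i, p in enumerate(range(2000, 18000, 3000))]
        )
        _m1, ids1 = feature_heatmap(track_of(vals), centers, 1500)
        _m2, ids2 = feature_heatmap(track_of(vals * 37.5), centers, 1500)
        assert ids1 == ids2


class TestExtendDomains:
    def test_midpoint_arithmetic(self):
        doms = IntervalSet(
            [("c", 1000, 2000, "ERD", None), ("c", 2000, 3000, "TZ", None),
             ("c", 3000, 4000, "LRD", None)]
        )
        out = extend_domains_to_tz_midpoints(doms)
        assert out.records == [
            ("c", 1000, 2500, "ERD", None),
            ("c", 2500, 4000, "LRD", None),
        ]

    def test_domain_at_chromosome_start(self):
        doms = IntervalSet(
            [("c", 0, 1000, "ERD", None), ("c", 1000, 2000, "TZ", None),
             ("c", 2000, 3000, "LRD", None)]
        )
        out = extend_domains_to_tz_midpoints(doms)
        assert out.records[0] == ("c", 0, 1500, "ERD", None)

    def test_symmetric_tz_flanks(self):
        doms = IntervalSet(
            [("c", 0, 1000, "TZ", None), ("c", 1000, 3000, "LRD", None),
             ("c", 3000, 4000, "TZ", None)]
        )
        out = extend_domains_to_tz_midpoints(doms)
        assert out.records == [("c", 500, 3500, "LRD", None)]

    def test_extended_domains_abut_at_midpoints(self):
        doms = IntervalSet(
            [("c", 0, 1000, "ERD", None), ("c", 1000, 2000, "TZ", None),
             ("c", 2000, 3000, "LRD", None), ("c", 3000, 5000, "TZ", None),
             ("c", 5000, 6000, "ERD", None)]
        )
        out = extend_domains_to_tz_midpoints(doms).records
        for (c1, s1, e1, *_), (c2, s2, e2, *_) in zip(out, out[1:]):
            assert e1 == s2

    def test_overlap_rejected(self):
        doms = IntervalSet(
            [("c", 0, 1000, "ERD", None), ("c", 500, 2000, "TZ", None)]
        )
        with pytest.raises(TimingError):
            extend_domains_to_tz_midpoints(doms)


class TestScaledProfile:
    def test_constant_track_constant_profiles(self):
        t = track_of([2.0] * 100)
        doms = IntervalSet([("c", 1000, 5000, "ERD", None), ("c", 6000, 9000, "LRD", None)])
        mat, _ids, meta = scaled_domain_profile(t, doms, 101)
        np.testing.assert_allclose(mat, 2.0)
        np.testing.assert_allclose(meta, 2.0)

    def test_linear_ramp_profile_is_linear(self):
        vals = np.arange(100, dtype=float)
        t = track_of(vals)
        doms = IntervalSet([("c", 2000, 8000, "ERD", None)])
        mat, _ids, _meta = scaled_domain_profile(t, doms, 61)
        diffs = np.diff(mat[0])
        np.testing.assert_allclose(diffs, diffs[0], rtol=1e-9)

    def test_size_invariance_of_scaled_shape(self):
        # two domains whose signal is the same function of relative position
        n = 1100
        vals = np.zeros(n)
        s1, e1 = 1000, 11000     # 10 kb domain
        s2, e2 = 20000, 120000   # 100 kb domain
        bw = 100
        for i in range(n):
            c = (i + 0.5) * bw
            if s1 <= c < e1:
                vals[i] = np.sin(np.pi * (c - s1) / (e1 - s1))
            elif s2 <= c < e2:
                vals[i] = np.sin(np.pi * (c - s2) / (e2 - s2))
        t = track_of(vals)
        doms = IntervalSet([("c", s1, e1, "d1", None), ("c", s2, e2, "d2", None)])
        mat, _ids, _meta = scaled_domain_profile(t, doms, 51)
        np.testing.assert_allclose(mat[0][5:-5], mat[1][5:-5], atol=0.02)

    def test_short_domain_error(self):
        t = track_of([1.0] * 10)
        with pytest.raises(TimingError):
            scaled_domain_profile(t, IntervalSet([("c", 0, 150, "d", None)]), 11)


class TestEnrichmentScore:
    def ranked(self, n):
        return RankedDomainList(tuple(f"d{i:02d}" for i in range(n)),
                                tuple(float(n - i) for i in range(n)))

    def test_top_query_es_one(self):
        r = self.ranked(10)
        es, _p = enrichment_score(r, {"d00", "d01", "d02"}, 99, rng_seed=0)
        assert np.isclose(es, 1.0)

    def test_bottom_query_es_minus_one(self):
        r = self.ranked(10)
        es, _p = enrichment_score(r, {"d07", "d08", "d09"}, 99, rng_seed=0)
        assert np.isclose(es, -1.0)

    def test_hand_enumerated_walk(self):
        """N=6, query at ranks 2 and 5: running sum peaks at +/-0.25; the
        positive deviation wins the magnitude tie."""
        r = self.ranked(6)
        es, _p = enrichment_score(r, {"d01", "d04"}, 99, rng_seed=0)
        assert np.isclose(es, 0.25)

    def test_empty_and_full_query_rejected(self):
        r = self.ranked(6)
        with pytest.raises(TimingError):
            enrichment_score(r, set(), 10, 0)
        with pytest.raises(TimingError):
            enrichment_score(r, set(r.ids), 10, 0)

    def test_pvalue_significant_for_perfect_separation(self):
        r = self.ranked(20)
        es, p = enrichment_score(r, {f"d{i:02d}" for i in range(10)}, 999, rng_seed=1)
        assert np.isclose(es, 1.0) and p < 0.05

    def test_reproducible_given_seed(self):
        r = self.ranked(12)
        a = enrichment_score(r, {"d00", "d05", "d07"}, 200, rng_seed=5)
        b = enrichment_score(r, {"d00", "d05", "d07"}, 200, rng_seed=5)
        assert a == b


class TestRankDomains:
    def test_ranking_and_tie_break(self):
        vals = np.zeros(100)
        vals[0:10] = 5.0
        vals[50:60] = 1.0
        t = track_of(vals)
        doms = IntervalSet(
            [("c", 0, 1000, "hi", None), ("c", 5000, 6000, "lo", None),
             ("c", 7000, 8000, "za", None), ("c", 8000, 9000, "zb", None)]
        )
        ranked = rank_domains(t, doms)
        assert ranked.ids[0].startswith("hi@")
        assert ranked.ids[1].startswith("lo@")
        # both zero-signal domains tie; id order breaks the tie
        assert list(ranked.ids[2:]) == sorted(ranked.ids[2:])
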