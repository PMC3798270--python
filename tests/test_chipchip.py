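"""Tiling-array normalization, peak calling, replicate logic and filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regulonscan import (
    BindingSiteCall,
    PeakRegion,
    ProbeTrack,
    call_percentile_regions,
    delta_strain_filter,
    intersect_replicates,
    median_smooth,
    quantile_normalize,
    rnap_crosslink_filter,
)
from regulonscan.simulate import simulate_array


def track_from(values, spacing=50, length=50):
    values = np.asarray(values, dtype=float)
    starts = np.arange(len(values)) * spacing
    return ProbeTrack(
        pd.DataFrame(
            {"chrom": "chr", "start": starts, "end": starts + length,
             "value": values}
        )
    )


class TestQuantileNormalize:
    def test_hand_example(self):
        a, b = quantile_normalize([track_from([1, 2, 3]), track_from([4, 5, 6])])
        assert np.allclose(a.values, [2.5, 3.5, 4.5])
        assert np.allclose(b.values, [2.5, 3.5, 4.5])

    def test_identical_tracks_unchanged(self):
        t = track_from([3.0, 1.0, 2.0])
        out = quantile_normalize([t, t])
        assert np.allclose(out[0].values, t.values)

    def test_order_preserved_within_track(self):
        a, b = quantile_normalize(
            [track_from([5, 1, 3]), track_from([10, 30, 20])]
        )
        assert np.argsort(a.values).tolist() == [1, 2, 0]
        assert np.argsort(b.values).tolist() == [0, 2, 1]

    def test_distribution_equality_after_normalization(self):
        rng = np.random.default_rng(1)
        a = track_from(rng.normal(size=200))
        b = track_from(np.exp(rng.normal(size=200)))  # monotone-warped scale
        na, nb = quantile_normalize([a, b])
        assert np.allclose(np.sort(na.values), np.sort(nb.values))

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False),
            min_size=3,
            max_size=40,
            unique=True,
        ),
        st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False),
            min_size=3,
            max_size=40,
            unique=True,
        ),
    )
    def test_idempotent(self, xs, ys):
        n = min(len(xs), len(ys))
        tracks = [track_from(xs[:n]), track_from(ys[:n])]
        once = quantile_normalize(tracks)
        twice = quantile_normalize(once)
        for t1, t2 in zip(once, twice):
            assert np.allclose(t1.values, t2.values)

    def test_mismatched_probes_rejected(self):
        a = track_from([1, 2, 3])
        b = track_from([1, 2, 3], spacing=60)
        with pytest.raises(ValueError, match="differs"):
            quantile_normalize([a, b])


class TestMedianSmooth:
    def test_constant_unchanged(self):
        t = track_from([2.0] * 20)
        assert np.allclose(median_smooth(t, 300).values, 2.0)

    def test_spike_removed(self):
        vals = [1.0] * 10
        vals[5] = 50.0
        out = median_smooth(track_from(vals), 300)
        assert np.allclose(out.values, 1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        t = track_from(rng.normal(size=60), spacing=37, length=20)
        window = 250
        out = median_smooth(t, window)
        centers = t.centers()
        vals = t.values
        expected = [
            np.median(vals[np.abs(centers - c) <= window / 2])
            for c in centers
        ]
        assert np.allclose(out.values, expected)


class TestPercentileRegions:
    def test_uniform_track_no_regions(self):
        assert call_percentile_regions(track_from([1.0] * 100)) == []

    def test_planted_run_recovered(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 0.2, size=200)
        vals[90:100] += 4.0
        regions = call_percentile_regions(track_from(vals), 95.0, 4)
        assert len(regions) == 1
        r = regions[0]
        assert r.start == 90 * 50 and r.end == 99 * 50 + 50
        assert r.start <= r.summit < r.end
        assert r.pvalue == pytest.approx(0.05**10)

    def test_min_run_filters_short_runs(self):
        vals = np.zeros(200)
        vals[50:52] = 5.0  # run of 2 < min_run 4
        assert call_percentile_regions(track_from(vals), 95.0, 4) == []

    def test_stringencies_nested(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(0, 0.3, size=400)
        for s in (100, 200, 300):
            vals[s : s + 8] += 3.0
        l2 = call_percentile_regions(track_from(vals), 95.0, 4)
        l3 = call_percentile_regions(track_from(vals), 98.0, 4)
        # the stricter threshold's regions lie inside the looser set
        for r3 in l3:
            assert any(
                r2.start <= r3.start and r3.end <= r2.end for r2 in l2
            )

    def test_output_disjoint_sorted(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=500)
        regions = call_percentile_regions(track_from(vals), 90.0, 2)
        for a, b in zip(regions, regions[1:]):
            assert a.end <= b.start


def region(start, end, score=1.0, chrom="chr"):
    return PeakRegion(chrom, start, end, (start + end) // 2, score)


class TestIntersectReplicates:
    def test_disjoint_replicates_empty(self):
        assert intersect_replicates(
            [[region(0, 100)], [region(200, 300)]]
        ) == []

    def test_identical_replicates_identity(self):
        rs = [region(50, 150), region(400, 500)]
        out = intersect_replicates([rs, rs])
        assert [(r.start, r.end) for r in out] == [(50, 150), (400, 500)]
        assert all(r.support >= {"rep1", "rep2"} for r in out)

    def test_staggered_overlap_union(self):
        out = intersect_replicates(
            [[region(100, 200)], [region(150, 250)]]
        )
        assert [(r.start, r.end) for r in out] == [(100, 250)]

    def test_matches_brute_force_interval_logic(self):
        rng = np.random.default_rng(13)

        def random_regions():
            rs = []
            pos = 0
            for _ in range(8):
                pos += int(rng.integers(20, 200))
                w = int(rng.integers(10, 150))
                rs.append(region(pos, pos + w))
                pos += w
            return rs

        reps = [random_regions(), random_regions(), random_regions()]
        out = intersect_replicates(reps)
        # brute force: per-bp coverage intersection
        L = max(r.end for rs in reps for r in rs) + 1
        cov = np.ones(L, dtype=bool)
        for rs in reps:
            c = np.zeros(L, dtype=bool)
            for r in rs:
                c[r.start : r.end] = True
            cov &= c
        expected_core = set(np.nonzero(cov)[0].tolist())
        got_core = set()
        for r in out:
            got_core.update(range(r.start, r.end))
        # every intersection bp is inside an output region, and every
        # output region contains at least one intersection bp
        assert expected_core <= got_core
        for r in out:
            assert any(cov[b] for b in range(r.start, r.end))


class TestDeltaStrainFilter:
    def test_no_control_no_flags(self):
        out = delta_strain_filter([region(0, 100)], [])
        assert out[0].filters == set()

    def test_overlap_flagged_coordinates_unchanged(self):
        out = delta_strain_filter(
            [region(0, 100), region(500, 600)], [region(90, 120)]
        )
        assert out[0].filters == {"delta_control_fail"}
        assert out[1].filters == set()
        assert (out[0].start, out[0].end) == (0, 100)


class TestRnapCrosslinkFilter:
    def make_tracks(self, arca, rnap, aerobic):
        return (
            track_from(arca, spacing=100, length=100),
            track_from(rnap, spacing=100, length=100),
            track_from(aerobic, spacing=100, length=100),
        )

    def test_artifact_region_flagged(self):
        n = 60
        arca = np.full(n, 0.1)
        rnap = np.full(n, 0.1)
        aero = np.full(n, 0.1)
        arca[10:20] = np.linspace(2.5, 3.5, 10)  # tracks RNAP
        rnap[10:20] = np.linspace(2.5, 3.5, 10)
        aero[10:20] = arca[10:20]  # condition-independent
        a, r, o = self.make_tracks(arca, rnap, aero)
        regions = [region(1000, 2000), region(4000, 4500)]
        out, report = rnap_crosslink_filter(
            regions, a, r, 300, 1.75, aerobic_track=o
        )
        assert "rnap_crosslink_fail" in out[0].filters
        assert out[1].filters == set()
        assert report["r"] is not None

    def test_condition_dependent_region_not_flagged(self):
        n = 60
        arca = np.full(n, 0.1)
        rnap = np.full(n, 0.1)
        aero = np.full(n, 0.1)
        arca[10:20] = np.linspace(2.5, 3.5, 10)
        rnap[10:20] = np.linspace(2.5, 3.5, 10)
        aero[10:20] = 0.3  # occupancy collapses aerobically: a real site
        a, r, o = self.make_tracks(arca, rnap, aero)
        out, _ = rnap_crosslink_filter(
            [region(1000, 2000)], a, r, 300, 1.75, aerobic_track=o
        )
        assert out[0].filters == set()

    def test_box_call_rescues_region(self):
        n = 60
        arca = np.full(n, 0.1)
        rnap = np.full(n, 0.1)
        aero = np.full(n, 0.1)
        arca[10:20] = rnap[10:20] = np.linspace(2.5, 3.5, 10)
        aero[10:20] = arca[10:20]
        a, r, o = self.make_tracks(arca, rnap, aero)
        box = BindingSiteCall("chr", 1200, 1218, "+", 12.0)
        out, _ = rnap_crosslink_filter(
            [region(1000, 2000)], a, r, 300, 1.75, aerobic_track=o,
            box_calls=[box],
        )
        assert out[0].filters == set()

    def test_few_bins_no_flags(self):
        a, r, o = self.make_tracks([0.1] * 20, [0.1] * 20, [0.1] * 20)
        out, report = rnap_crosslink_filter(
            [region(100, 400)], a, r, 300, 1.75, aerobic_track=o
        )
        assert report["r"] is None
        assert out[0].filters == set()


class TestEndToEndArray:
    def test_planted_sensitivity_and_specificity(self):
        # effect 2.0, noise 0.3: every planted site found, nothing else
        centers = [5000, 15000, 30000]
        tracks, record = simulate_array(
            40000, centers, effect_log2=2.0, noise_sd=0.3, seed=21
        )
        regions = call_percentile_regions(tracks["anaerobic"], 95.0, 4)
        assert len(regions) == len(centers)
        for c, r in zip(sorted(centers), regions):
            assert r.start <= c <= r.end

    def test_rnap_artifact_flagged_end_to_end(self):
        tracks, record = simulate_array(
            40000, [5000], effect_log2=2.0, noise_sd=0.2, seed=5,
            rnap_regions=[(20000, 20500)], rnap_effect=3.0,
        )
        regions = call_percentile_regions(tracks["anaerobic"], 95.0, 4)
        out, _ = rnap_crosslink_filter(
            regions, tracks["anaerobic"], tracks["rnap"], 300, 1.75,
            aerobic_track=tracks["aerobic"],
        )
        flagged = [r for r in out if "rnap_crosslink_fail" in r.filters]
        clean = [r for r in out if not r.filters]
        assert any(20000 <= r.summit < 20500 for r in flagged)
        assert any(abs(r.summit - 5000) < 500 for r in clean)
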