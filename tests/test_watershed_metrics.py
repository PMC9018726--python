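import numpy as np
import pytest

from tidechan import network_graph as ng
from tidechan import watershed_metrics as wm
from tidechan.scene_io import RasterGrid
from tidechan.synthetic_data import SyntheticSpec, generate_network

from conftest import make_mask, nearest_channel_oracle


def _extract(mask, seaward="bottom"):
    net = ng.build_network(ng.skeletonize(mask))
    ng.identify_outlets(net, mask, seaward)
    return ng.assign_strahler(net)


class TestDelineate:
    def test_two_parallel_channels_split_with_tie_to_smaller_id(self):
        chan = np.zeros((21, 21), dtype=np.uint8)
        chan[:, 0] = 1
        chan[:, 20] = 1
        mask = make_mask(chan)
        net = _extract(mask)
        sheds = wm.delineate_watersheds(mask, net)
        labels = sheds.labels.values
        assert (labels[:, :11] == 1).all()  # tie column 10 goes to id 1
        assert (labels[:, 11:] == 2).all()

    def test_single_component_covers_aoi(self, y_mask):
        net = _extract(y_mask)
        sheds = wm.delineate_watersheds(y_mask, net)
        assert set(np.unique(sheds.labels.values)) == {1}

    def test_partition_sums_to_aoi_area(self):
        spec = SyntheticSpec(domain_shape=(250, 250), n_outlets=3, seed=14)
        _, mask, _ = generate_network(spec)
        net = _extract(mask)
        sheds = wm.delineate_watersheds(mask, net)
        assert sum(sheds.areas.values()) == pytest.approx(
            float(mask.aoi.sum()) * mask.pixel_size**2
        )

    def test_no_channels_single_watershed_warns(self, caplog):
        mask = make_mask(np.zeros((10, 10)))
        with caplog.at_level("WARNING", logger="tidechan"):
            sheds = wm.delineate_watersheds(mask, ng.ChannelNetwork(1.0))
        assert list(sheds.areas) == [0]
        assert "no channel pixels" in caplog.text

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            chan = np.zeros((30, 30), dtype=np.uint8)
            # a few random channel strokes
            for _ in range(int(rng.integers(2, 5))):
                r, c = rng.integers(0, 25, 2)
                if rng.random() < 0.5:
                    chan[r, c : c + int(rng.integers(3, 6))] = 1
                else:
                    chan[r : r + int(rng.integers(3, 6)), c] = 1
            if not chan.any():
                continue
            mask = make_mask(chan)
            net = _extract(mask)
            sheds = wm.delineate_watersheds(mask, net)
            seeds = wm._component_seeds(mask, net)
            _, owner = nearest_channel_oracle(chan, seeds)
            np.testing.assert_array_equal(sheds.labels.values, owner)


class TestUnchanneledDistance:
    def test_column_channel_linear_distances(self):
        chan = np.zeros((5, 11), dtype=np.uint8)
        chan[:, 0] = 1
        dist = wm.unchanneled_distance(make_mask(chan))
        for i in range(11):
            assert dist.values[2, i] == pytest.approx(float(i))

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            chan = (rng.random((20, 20)) < 0.1).astype(np.uint8)
            if not chan.any():
                continue
            mask = make_mask(chan)
            dist = wm.unchanneled_distance(mask)
            expect, _ = nearest_channel_oracle(chan, {1: chan.astype(bool)})
            np.testing.assert_allclose(dist.values, expect, atol=1e-9)

    def test_scales_with_pixel_size(self):
        chan = np.zeros((8, 8), dtype=np.uint8)
        chan[0, 0] = 1
        d1 = wm.unchanneled_distance(make_mask(chan, pixel_size=1.0)).values
        d3 = wm.unchanneled_distance(make_mask(chan, pixel_size=3.0)).values
        np.testing.assert_allclose(d3, 3.0 * d1)

    def test_empty_channel_errors(self):
        with pytest.raises(ValueError):
            wm.unchanneled_distance(make_mask(np.zeros((5, 5))))


class TestComputeMetrics:
    def test_strip_watershed_closed_form(self):
        # channel along col 0, platform cols 1..10, pixel 1 m -> mUpl = 5.5
        chan = np.zeros((11, 11), dtype=np.uint8)
        chan[:, 0] = 1
        mask = make_mask(chan)
        net = _extract(mask, seaward="left")
        sheds = wm.delineate_watersheds(mask, net)
        dist = wm.unchanneled_distance(mask)
        (rec,) = wm.compute_metrics(sheds, net, dist, mask, "s", "saltmarsh")
        assert rec.mupl == pytest.approx(5.5)
        assert rec.drainage_density == pytest.approx(rec.total_length_m / rec.area_m2)
        assert rec.hortonian_length == pytest.approx(1.0 / rec.drainage_density)
        assert rec.geometric_efficiency == pytest.approx(rec.hortonian_length / 5.5)

    def test_bisecting_channel_quarter_width(self):
        # channel row bisecting a strip of height 2k+1: discrete mean (k+1)/2
        k = 10
        chan = np.zeros((2 * k + 1, 30), dtype=np.uint8)
        chan[k, :] = 1
        mask = make_mask(chan)
        dist = wm.unchanneled_distance(mask)
        platform = mask.aoi & ~mask.channel
        assert dist.values[platform].mean() == pytest.approx((k + 1) / 2)

    def test_zero_length_watershed_missing_values(self):
        chan = np.zeros((20, 20), dtype=np.uint8)
        chan[10, 10] = 1  # isolated single pixel: node but no edges
        chan[0:10, 2] = 1
        mask = make_mask(chan)
        net = _extract(mask)
        sheds = wm.delineate_watersheds(mask, net)
        dist = wm.unchanneled_distance(mask)
        records = wm.compute_metrics(sheds, net, dist, mask, "s", "saltmarsh")
        degenerate = [r for r in records if r.total_length_m == 0]
        assert degenerate
        for r in degenerate:
            assert r.drainage_density == 0.0
            assert r.hortonian_length is None
            assert r.geometric_efficiency is None

    def test_ge_invariant_under_rescaling(self, y_mask):
        recs = {}
        for ps in (1.0, 3.0):
            mask = make_mask(y_mask.channel, pixel_size=ps)
            net = _extract(mask)
            sheds = wm.delineate_watersheds(mask, net)
            dist = wm.unchanneled_distance(mask)
            (rec,) = wm.compute_metrics(sheds, net, dist, mask, "s", "m")
            recs[ps] = rec
        assert recs[1.0].geometric_efficiency == pytest.approx(
            recs[3.0].geometric_efficiency
        )
        assert recs[3.0].mupl == pytest.approx(3.0 * recs[1.0].mupl)


class TestWetlandDrainageDensity:
    def test_totals(self):
        recs = [
            wm.MetricRecord(1, "", "", 1000.0, 100.0, 0.1, None, None, None),
            wm.MetricRecord(2, "", "", 500.0, 50.0, 0.1, None, None, None),
        ]
        assert wm.wetland_drainage_density(recs, 1500.0) == pytest.approx(0.1)

    def test_equals_area_weighted_mean(self):
        recs = [
            wm.MetricRecord(1, "", "", 1000.0, 100.0, 0.1, None, None, None),
            wm.MetricRecord(2, "", "", 3000.0, 60.0, 0.02, None, None, None),
        ]
        total_area = 4000.0
        dd = wm.wetland_drainage_density(recs, total_area)
        weighted = sum(r.drainage_density * r.area_m2 for r in recs) / total_area
        assert dd == pytest.approx(weighted)

    def test_empty_network_zero(self):
        assert wm.wetland_drainage_density(ng.ChannelNetwork(1.0), 100.0) == 0.0

    def test_rejects_nonpositive_area(self):
        with pytest.raises(ValueError):
            wm.wetland_drainage_density([], 0.0)


class TestSummaries:
    def _records(self):
        out = []
        for i, (loc, wtype, d_vals) in enumerate(
            [
                ("loc1", "saltmarsh", [0.1, 0.3]),
                ("loc2", "saltmarsh", [0.2]),
                ("loc3", "mangrove", [0.05, 0.07]),
            ]
        ):
            for j, d in enumerate(d_vals):
                out.append(
                    wm.MetricRecord(j, loc, wtype, 1000.0, d * 1000.0, d, 5.0, 1 / d, 2.0)
                )
        return out

    def test_location_mean_and_se(self):
        per_loc, per_type = wm.summarize_locations(self._records())
        assert per_loc.loc["loc1", "drainage_density_per_m_mean"] == pytest.approx(0.2)
        assert per_loc.loc["loc1", "drainage_density_per_m_se"] == pytest.approx(0.1)
        assert np.isnan(per_loc.loc["loc2", "drainage_density_per_m_se"])

    def test_type_vectors(self):
        _, per_type = wm.summarize_locations(self._records())
        assert len(per_type["saltmarsh"]) == 2
        assert len(per_type["mangrove"]) == 1

    def test_eight_and_seven_locations(self):
        # per-type vectors sized like the study's 8 + 7 systems
        records = []
        for i in range(8):
            records.append(wm.MetricRecord(0, f"s{i}", "saltmarsh", 1e3, 10.0, 0.01, 5.0, 100.0, 2.0))
        for i in range(7):
            records.append(wm.MetricRecord(0, f"m{i}", "mangrove", 1e3, 10.0, 0.01, 5.0, 100.0, 2.0))
        _, per_type = wm.summarize_locations(records)
        assert len(per_type["saltmarsh"]) == 8
        assert len(per_type["mangrove"]) == 7
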