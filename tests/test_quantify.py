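"""Soma detection, strict co-location, region rollup, cross-brain statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from wvt import synthetic
from wvt.quantify import (AtlasVolume, ColocatedPairs, Soma, SomaSet,
                          aggregate_brains, coloc_proportions, colocate,
                          count_by_region, detect_somas)


def _soma_set(coords, channel="green"):
    return SomaSet(somas=[Soma(id=i + 1, x=c[0], y=c[1], z=c[2], channel=channel)
                          for i, c in enumerate(coords)], channel=channel)


class TestDetectSomas:
    def test_planted_somas_recovered(self):
        rng = np.random.default_rng(4)
        shape, voxel = (64, 256, 256), (1.0, 1.0, 2.0)
        coords = []
        while len(coords) < 200:
            p = [rng.uniform(15, 240), rng.uniform(15, 240), rng.uniform(15, 112)]
            if all((p[0] - c[0]) ** 2 + (p[1] - c[1]) ** 2 + (p[2] - c[2]) ** 2 > 15 ** 2
                   for c in coords):
                coords.append(p)
        coords = np.array(coords)
        vol = synthetic.render_soma_volume(coords, shape, voxel, snr=10, seed=5)
        detected = detect_somas(vol, voxel, block_shape=(64, 128, 128))
        det = detected.coords()
        recall = (cKDTree(det).query(coords)[0] < 4.0).mean()
        precision = (cKDTree(coords).query(det)[0] < 4.0).mean()
        assert recall >= 0.95
        assert precision >= 0.95

    def test_empty_volume(self):
        assert len(detect_somas(np.zeros((8, 16, 16)))) == 0

    def test_block_straddling_soma_detected_once(self):
        coords = np.array([[128.0, 128.0, 64.0]])  # dead on the block seams
        vol = synthetic.render_soma_volume(coords, (64, 256, 256), (1, 1, 2),
                                           snr=0, seed=1)
        detected = detect_somas(vol, (1, 1, 2), block_shape=(64, 128, 128))
        assert len(detected) == 1
        np.testing.assert_allclose(detected.coords()[0], coords[0], atol=2.0)


class TestColocate:
    def test_close_pair_matched(self):
        g = _soma_set([(10, 10, 10)])
        r = _soma_set([(10.3, 10.4, 10.0)], "red")
        pairs = colocate(g, r)
        assert len(pairs) == 1
        assert pairs.pairs[0][2] == pytest.approx(0.5)

    def test_exactly_one_micron_excluded(self):
        g = _soma_set([(10, 10, 10)])
        r = _soma_set([(11.0, 10.0, 10.0)], "red")  # distance exactly 1.0 μm
        assert len(colocate(g, r)) == 0

    def test_just_under_threshold_included(self):
        g = _soma_set([(10, 10, 10)])
        r = _soma_set([(10.9999, 10.0, 10.0)], "red")
        assert len(colocate(g, r)) == 1

    def test_planted_pairs_exactly_recovered(self):
        green, red, truth = synthetic.make_soma_populations(
            2000, 2000, coloc_fraction=0.02, bounds_um=(1000, 1000, 500), seed=8)
        pairs = colocate(green, red)
        assert len(pairs) == len(truth) == 40
        assert {(g, r) for g, r, _ in pairs.pairs} == {(g, r) for g, r, _ in truth.pairs}

    def test_symmetry_under_swap(self):
        green, red, _ = synthetic.make_soma_populations(
            300, 300, coloc_fraction=0.05, bounds_um=(500, 500, 250), seed=2)
        fwd = colocate(green, red)
        rev = colocate(red, green)
        assert {(g, r) for g, r, _ in fwd.pairs} == {(r, g) for g, r, _ in rev.pairs}

    def test_one_to_one_matching(self):
        # two greens near one red: only the mutual nearest pair is emitted
        g = _soma_set([(0, 0, 0), (0.6, 0, 0)])
        r = _soma_set([(0.25, 0, 0)], "red")
        pairs = colocate(g, r)
        assert len(pairs) == 1
        assert pairs.pairs[0][0] == 1  # the closer green
        ids_g = [p[0] for p in pairs.pairs]
        assert len(ids_g) == len(set(ids_g))

    def test_duplicate_pair_id_rejected(self):
        with pytest.raises(Exception):
            ColocatedPairs(pairs=[(1, 1, 0.5), (1, 2, 0.4)])


class TestCountByRegion:
    def test_all_in_one_region(self):
        atlas = synthetic.make_atlas(n_regions=3)
        coords = [(50.0, 50.0, 50.0), (100.0, 200.0, 100.0)]  # both in slab 1
        report = count_by_region(_soma_set(coords), atlas)
        row = report.table[report.table["region_id"] == 1].iloc[0]
        assert row["count"] == 2 and row["proportion_pct"] == 100.0

    def test_planted_60_30_10_split(self):
        atlas = synthetic.make_atlas(n_regions=3)
        # slabs along x: [0,426.7), [426.7,853.3), [853.3,1280) μm
        coords = ([(100.0, 50, 50)] * 60 + [(600.0, 50, 50)] * 30 + [(1000.0, 50, 50)] * 10)
        coords = [(x + i * 1e-3, y, z) for i, (x, y, z) in enumerate(coords)]
        report = count_by_region(_soma_set(coords), atlas)
        props = dict(zip(report.table["region_id"], report.table["proportion_pct"]))
        assert props[1] == pytest.approx(60.0)
        assert props[2] == pytest.approx(30.0)
        assert props[3] == pytest.approx(10.0)

    def test_voxel_boundary_floor_convention(self):
        atlas = synthetic.make_atlas(shape=(4, 4, 4), voxel_size_um=(10, 10, 10),
                                     n_regions=2)
        # x=20.0 is the first voxel of the second slab (floor convention)
        assert atlas.label_at(20.0, 5.0, 5.0) == 2
        assert atlas.label_at(19.999, 5.0, 5.0) == 1

    def test_background_soma_goes_to_unassigned(self):
        atlas = synthetic.make_atlas(n_regions=2)
        outside = _soma_set([(99999.0, 0.0, 0.0)])
        report = count_by_region(outside, atlas)
        row = report.table[report.table["region_name"] == "unassigned"].iloc[0]
        assert row["count"] == 1

    def test_hierarchy_rollup_consistency(self):
        atlas = synthetic.make_atlas(n_regions=4, n_parents=2)
        rng = np.random.default_rng(0)
        coords = [(rng.uniform(0, 1280), rng.uniform(0, 1280), rng.uniform(0, 640))
                  for _ in range(200)]
        somas = _soma_set(coords)
        sub = count_by_region(somas, atlas, level="subregion")
        parent = count_by_region(somas, atlas, level="region")
        for pid in parent.table["region_id"]:
            children = [rid for rid, e in atlas.hierarchy.items() if e["parent_id"] == pid]
            child_sum = sub.table[sub.table["region_id"].isin(children)]["proportion_pct"].sum()
            got = float(parent.table[parent.table["region_id"] == pid]["proportion_pct"].iloc[0])
            assert got == pytest.approx(child_sum, abs=1e-9)


class TestAggregateBrains:
    def _report(self, props):
        atlas = synthetic.make_atlas(n_regions=len(props))
        table = pd.DataFrame({
            "region_id": np.arange(1, len(props) + 1),
            "region_name": [f"sub_{i+1}" for i in range(len(props))],
            "level": "subregion",
            "count": [int(p) for p in props],
            "proportion_pct": props,
        })
        from wvt.quantify import RegionReport
        return RegionReport(table=table, level="subregion", n_somas=int(sum(props)))

    def test_identical_reports_zero_sem(self):
        rep = aggregate_brains([self._report([60.0, 40.0])] * 4)
        assert (rep.table["sem_pct"] == 0.0).all()
        assert rep.n_brains == 4

    def test_known_sem(self):
        reports = [self._report([p, 100 - p]) for p in (10.0, 12.0, 8.0, 10.0)]
        rep = aggregate_brains(reports)
        row = rep.table[rep.table["region_id"] == 1].iloc[0]
        assert row["mean_pct"] == pytest.approx(10.0)
        assert row["sem_pct"] == pytest.approx(0.8165, abs=1e-3)

    def test_missing_region_counts_as_zero(self):
        r1 = self._report([100.0, 0.0])
        r2 = self._report([50.0, 50.0])
        r2.table = r2.table[r2.table["region_id"] == 1]  # region 2 absent in brain 2
        rep = aggregate_brains([r1, r2])
        row2 = rep.table[rep.table["region_id"] == 2].iloc[0]
        assert row2["mean_pct"] == pytest.approx(0.0)

    def test_single_brain_flagged(self):
        rep = aggregate_brains([self._report([70.0, 30.0])])
        assert rep.single_brain_sem_flag
        assert (rep.table["sem_pct"] == 0.0).all()


class TestColocProportions:
    def test_arithmetic(self):
        green = _soma_set([(i * 10.0, 0, 0) for i in range(1000)])
        red = _soma_set([(i * 10.0 + 5, 5, 5) for i in range(900)], "red")
        pairs = ColocatedPairs(pairs=[(1, 1, 0.5), (2, 2, 0.4)])
        pg, pr = coloc_proportions(pairs, green, red)
        assert pg == pytest.approx(0.20)
        assert pr == pytest.approx(2 / 9)

    def test_zero_pairs(self):
        g = _soma_set([(0, 0, 0)])
        r = _soma_set([(50, 50, 50)], "red")
        assert coloc_proportions(colocate(g, r), g, r) == (0.0, 0.0)

    def test_empty_set_gives_nan(self):
        g = _soma_set([])
        r = _soma_set([(0, 0, 0)], "red")
        pg, pr = coloc_proportions(ColocatedPairs(), g, r)
        assert np.isnan(pg) and pr == 0.0
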