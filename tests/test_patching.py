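import numpy as np
import pytest
from shapely.geometry import Polygon, box

from fscchange.exceptions import EdgeError, MaskedPatchError
from fscchange.geo_io import FSCRecord, GridTransform, MultispectralScene
from fscchange.patching import (
    PatchSample,
    anchor_point,
    extract_patch,
    split_by_area,
    train_test_split,
)


def _raster(shape=(9, 9), value=0.3, nbands=1):
    return MultispectralScene(
        band_stack=np.full((*shape, nbands), value, dtype=np.float32),
        band_names=tuple(f"B{i}" for i in range(nbands)),
        transform=GridTransform(0.0, 0.0, 10.0),
        crs_id="EPSG:32648",
        nodata_mask=np.zeros(shape, dtype=bool),
        epoch="e1",
    )


def _rec(geom, area=None, fsc_id="x"):
    return FSCRecord(fsc_id, geom, area if area is not None else geom.area, {"e1": "Arbor"})


class TestAnchorPoint:
    def test_square_centroid(self):
        pt = anchor_point(_rec(box(0, 0, 10, 10)))
        assert (pt.x, pt.y) == (5, 5)

    def test_triangle_centroid(self):
        pt = anchor_point(_rec(Polygon([(0, 0), (30, 0), (0, 30)])))
        assert (pt.x, pt.y) == (10, 10)

    def test_concave_polygon_returns_interior_point(self):
        c_shape = Polygon([
            (0, 0), (30, 0), (30, 10), (10, 10), (10, 20), (30, 20), (30, 30), (0, 30)
        ])
        centroid = c_shape.centroid
        pt = anchor_point(_rec(c_shape))
        if not c_shape.contains(centroid):
            assert c_shape.contains(pt)
        assert c_shape.contains(pt)


class TestExtractPatch:
    def test_constant_raster(self):
        scene = _raster()
        patch = extract_patch(scene, _rec(box(0, -90, 90, 0)))
        assert patch.window.shape == (5, 5, 1)
        assert np.all(patch.window == np.float32(0.3))

    def test_center_pixel_window_covers_whole_small_raster(self):
        scene = _raster(shape=(5, 5))
        # centroid of the full extent maps to pixel (2, 2)
        patch = extract_patch(scene, _rec(box(0, -50, 50, 0)))
        assert patch.center_rowcol == (2, 2)
        assert patch.window.shape == (5, 5, 1)

    def test_window_crossing_edge_raises(self):
        scene = _raster(shape=(5, 5))
        # small polygon near the top-left corner: anchor at pixel (1, 1)
        with pytest.raises(EdgeError):
            extract_patch(scene, _rec(box(5, -25, 25, -5)))

    def test_nodata_window_excluded(self):
        scene = _raster()
        scene.nodata_mask[4, 4] = True
        with pytest.raises(MaskedPatchError):
            extract_patch(scene, _rec(box(0, -90, 90, 0)))


class TestAreaFilter:
    def test_strict_threshold(self):
        square = box(0, 0, 10, 10)
        records = [_rec(square, a, str(a)) for a in (2999, 3000, 3001)]
        eligible, ood = split_by_area(records)
        assert [r.fsc_id for r in eligible] == ["3001"]
        assert sorted(r.fsc_id for r in ood) == ["2999", "3000"]

    def test_partition_is_exhaustive(self, scene_pair):
        _, _, _, records = scene_pair
        eligible, ood = split_by_area(records)
        assert len(eligible) + len(ood) == len(records)
        assert not {r.fsc_id for r in eligible} & {r.fsc_id for r in ood}


def _samples(labels, in_dist=True):
    return [
        PatchSample(str(i), np.zeros((5, 5, 1)), (2, 2), "e1", in_dist, label)
        for i, label in enumerate(labels)
    ]


class TestTrainTestSplit:
    def test_80_20_counts(self):
        train, test = train_test_split(_samples(["Arbor"] * 100), 0.8, seed=0)
        assert (len(train), len(test)) == (80, 20)

    def test_deterministic_under_seed(self):
        samples = _samples(["Arbor"] * 50 + ["Shrub"] * 50)
        a = train_test_split(samples, 0.8, seed=7)
        b = train_test_split(samples, 0.8, seed=7)
        assert [s.fsc_id for s in a[0]] == [s.fsc_id for s in b[0]]

    def test_stratification_preserves_ratio(self):
        samples = _samples(["Arbor"] * 50 + ["Shrub"] * 50)
        train, test = train_test_split(samples, 0.8, seed=0)
        assert sum(s.label == "Arbor" for s in train) == 40
        assert sum(s.label == "Arbor" for s in test) == 10

    def test_tiny_class_kept_whole_in_training(self, caplog):
        samples = _samples(["Arbor"] * 20 + ["Bare"])
        with caplog.at_level("WARNING"):
            train, test = train_test_split(samples, 0.8, seed=0)
        assert sum(s.label == "Bare" for s in train) == 1
        assert "Bare" in caplog.text

    def test_out_of_distribution_never_trains(self):
        samples = _samples(["Arbor"] * 20) + _samples(["Shrub"] * 5, in_dist=False)
        train, test = train_test_split(samples, 0.8, seed=0)
        assert all(s.in_distribution for s in train)
        assert sum(not s.in_distribution for s in test) == 5


class TestWindowGeometry:
    def test_patch_centers_lie_inside_their_polygons(self, scene_pair):
        _, s1, _, records = scene_pair
        checked = 0
        for rec in records:
            try:
                patch = extract_patch(s1, rec)
            except (EdgeError, MaskedPatchError):
                continue
            x, y = s1.transform.pixel_center(*patch.center_rowcol)
            from shapely.geometry import Point
            assert rec.geometry.contains(Point(x, y)), rec.fsc_id
            checked += 1
        assert checked > 100

    def test_large_polygons_contain_their_full_window(self):
        """For FSCs above ~1 ha, all 25 sampled pixel centers of the 5×5
        window should be interior in ≥95% of cases — the premise that
        centroid patches of large FSCs avoid neighboring-FSC pixels."""
        from shapely.geometry import Point

        from fscchange.synthetic import SceneConfig, generate_scene_pair

        inside = total = 0
        for seed in range(5):
            cfg = SceneConfig(grid_shape=(128, 128), n_fsc=150,
                              change_fraction=0.08, seed=seed)
            s1, _, records = generate_scene_pair(cfg)
            for rec in records:
                if rec.area_m2 < 10000:
                    continue
                try:
                    patch = extract_patch(s1, rec)
                except (EdgeError, MaskedPatchError):
                    continue
                r, c = patch.center_rowcol
                total += 1
                inside += all(
                    rec.geometry.contains(
                        Point(*s1.transform.pixel_center(r + dr, c + dc))
                    )
                    for dr in range(-2, 3)
                    for dc in range(-2, 3)
                )
        assert total >= 100
        assert inside / total >= 0.95
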