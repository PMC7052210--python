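"""Patch segmentation, slice metrics and the density heat map."""

import numpy as np
import pandas as pd
import pytest

from hscquant import (
    ChannelImage,
    CollagenMask,
    PatchSet,
    TissueMask,
    density_heatmap,
    segment_cf,
    segment_rf,
    slice_metrics,
)
from hscquant.quantify import render_heatmap

from conftest import flood_fill_labels, same_partition


def _field(pixels, px=1.0, channel="RF"):
    return ChannelImage(np.asarray(pixels, dtype=float), px, channel)


def _full_tissue(shape, px=1.0):
    return TissueMask(np.ones(shape, dtype=bool), px)


def _patchset_from_centroids(centroids_um, px=1.0, shape=(400, 400)):
    """Minimal PatchSet with prescribed centroids (for heat-map tests)."""
    rows = [
        {
            "id": i + 1,
            "area_um2": 1.0,
            "centroid_x_um": x,
            "centroid_y_um": y,
            "bbox_min_row": 0,
            "bbox_min_col": 0,
            "bbox_max_row": 1,
            "bbox_max_col": 1,
        }
        for i, (x, y) in enumerate(centroids_um)
    ]
    return PatchSet(
        label_image=np.zeros(shape, dtype=int),
        patches=pd.DataFrame(rows) if rows else pd.DataFrame(
            columns=["id", "area_um2", "centroid_x_um", "centroid_y_um",
                     "bbox_min_row", "bbox_min_col", "bbox_max_row",
                     "bbox_max_col"]
        ),
        tissue_area_mm2=shape[0] * shape[1] * px**2 / 1e6,
        pixel_size_um=px,
    )


class TestSegmentRF:
    def test_all_zero_rf_gives_no_patches(self):
        rf = _field(np.zeros((64, 64)))
        patches = segment_rf(rf, _full_tissue((64, 64)))
        assert patches.count == 0
        assert patches.total_area_um2 == 0.0

    def test_disjoint_disks_counted_with_exact_areas(self):
        img = np.zeros((200, 200))
        yy, xx = np.mgrid[:200, :200]
        centers = [(30, 30), (30, 160), (100, 100), (170, 40), (170, 170)]
        expected_areas = []
        for cy, cx in centers:
            d = (yy - cy) ** 2 + (xx - cx) ** 2 <= 10**2
            img[d] = 100.0
            expected_areas.append(d.sum())
        patches = segment_rf(
            _field(img), _full_tissue((200, 200)), threshold=50.0
        )
        assert patches.count == 5
        assert sorted(patches.patches["area_um2"]) == sorted(
            float(a) for a in expected_areas
        )
        lab_oracle, n_oracle = flood_fill_labels(img > 50.0)
        assert n_oracle == 5
        assert same_partition(patches.label_image, lab_oracle)

    def test_diagonal_contact_merges_under_8_connectivity(self):
        img = np.zeros((20, 20))
        img[5:8, 5:8] = 100.0
        img[8:11, 8:11] = 100.0  # touches only at the corner pixel diagonal
        patches = segment_rf(
            _field(img), _full_tissue((20, 20)), threshold=50.0,
            min_area_um2=1.0,
        )
        assert patches.count == 1

    def test_empty_tissue_mask_rejected(self):
        rf = _field(np.ones((16, 16)))
        with pytest.raises(ValueError, match="empty"):
            segment_rf(rf, TissueMask(np.zeros((16, 16), bool), 1.0))

    def test_small_components_dropped(self):
        img = np.zeros((50, 50))
        img[10, 10] = 100.0  # single pixel, 1 µm²
        img[30:40, 30:40] = 100.0  # 100 µm²
        patches = segment_rf(
            _field(img), _full_tissue((50, 50)), threshold=50.0,
            min_area_um2=10.0,
        )
        assert patches.count == 1
        assert patches.patches["area_um2"].iloc[0] == 100.0

    def test_lower_threshold_never_decreases_rf_area(self):
        rng = np.random.default_rng(11)
        img = rng.uniform(0, 100, (80, 80))
        tissue = _full_tissue((80, 80))
        areas = [
            segment_rf(_field(img), tissue, threshold=t,
                       min_area_um2=0.0).total_area_um2
            for t in (80.0, 60.0, 40.0, 20.0)
        ]
        assert areas == sorted(areas)


class TestSegmentCF:
    def test_all_zero_cf_gives_empty_mask(self):
        cf = _field(np.zeros((32, 32)), channel="CF_SHG")
        mask = segment_cf(cf, _full_tissue((32, 32)))
        assert not mask.mask.any()
        assert mask.cf_area_mm2 == 0.0

    def test_mask_restricted_to_tissue(self):
        img = np.full((40, 40), 100.0)
        tissue = np.zeros((40, 40), bool)
        tissue[10:30, 10:30] = True
        mask = segment_cf(
            _field(img, channel="CF_SHG"),
            TissueMask(tissue, 1.0),
            threshold=50.0,
        )
        assert (mask.mask <= tissue).all()

    def test_fiber_area_matches_generator_truth(self, small_field):
        rf, cf, truth, tissue = small_field
        mask = segment_cf(cf, tissue, min_area_um2=0.0)
        got_fraction = mask.cf_area_mm2 / tissue.tissue_area_mm2
        assert got_fraction == pytest.approx(
            truth.true_cf_area_fraction, abs=1e-6
        )


class TestSliceMetrics:
    def test_rf_covering_tissue_gives_100_percent(self):
        img = np.full((60, 60), 100.0)
        tissue = _full_tissue((60, 60))
        patches = segment_rf(_field(img), tissue, threshold=50.0)
        cf = segment_cf(_field(np.zeros((60, 60)), channel="CF_SHG"), tissue)
        m = slice_metrics(patches, cf, tissue)
        assert m.rf_area_pct == pytest.approx(100.0)

    def test_density_is_count_over_tissue_area(self):
        # 62 patches on exactly 1.0 mm² of tissue -> 62 per mm²
        centroids = [(10.0 * i + 5.0, 10.0 * (i % 7) + 5.0) for i in range(62)]
        patches = _patchset_from_centroids(centroids, px=1.0, shape=(1000, 1000))
        tissue = _full_tissue((1000, 1000))
        cf = CollagenMask(np.zeros((1000, 1000), bool), 1.0)
        m = slice_metrics(patches, cf, tissue)
        assert m.tissue_area_mm2 == pytest.approx(1.0)
        assert m.rf_patch_density_per_mm2 == pytest.approx(62.0)

    def test_patches_on_collagen_have_zero_distance(self):
        img = np.zeros((100, 100))
        img[20:30, 20:30] = 100.0
        img[60:70, 60:70] = 100.0
        tissue = _full_tissue((100, 100))
        patches = segment_rf(_field(img), tissue, threshold=50.0)
        collagen = CollagenMask(img > 50.0, 1.0)  # collagen == patches
        m = slice_metrics(patches, collagen, tissue)
        assert m.proximity["fraction_patches_near_collagen"] == 1.0
        assert m.proximity["median_nearest_distance_um"] == 0.0

    def test_histogram_counts_sum_to_patch_count(self, small_field):
        rf, cf, truth, tissue = small_field
        patches = segment_rf(rf, tissue)
        collagen = segment_cf(cf, tissue)
        m = slice_metrics(patches, collagen, tissue)
        assert m.size_histogram["count"].sum() == patches.count == truth.true_patch_count

    def test_zero_tissue_area_rejected(self):
        patches = _patchset_from_centroids([(5.0, 5.0)])
        cf = CollagenMask(np.zeros((400, 400), bool), 1.0)
        tissue = TissueMask(np.zeros((400, 400), bool), 1.0)
        with pytest.raises(ValueError):
            slice_metrics(patches, cf, tissue)


class TestDensityHeatmap:
    def test_no_patches_gives_zero_grid(self):
        dm = density_heatmap(_patchset_from_centroids([]))
        assert dm.grid.sum() == 0

    def test_three_centroids_in_one_cell(self):
        dm = density_heatmap(
            _patchset_from_centroids([(110.0, 120.0), (150.0, 199.0), (101.0, 101.0)])
        )
        assert dm.grid[1, 1] == 3
        assert dm.total == 3
        assert (dm.grid.sum() - dm.grid[1, 1]) == 0

    def test_boundary_centroid_goes_to_higher_cell(self):
        dm = density_heatmap(_patchset_from_centroids([(200.0, 50.0)]))
        assert dm.grid[0, 2] == 1
        assert dm.total == 1

    def test_grid_sum_equals_patch_count_on_synthetic_field(self, small_field):
        rf, cf, truth, tissue = small_field
        patches = segment_rf(rf, tissue)
        dm = density_heatmap(patches, cell_size_um=100.0)
        assert dm.total == patches.count == truth.true_patch_count

    def test_render_writes_png(self, tmp_path, small_field):
        rf, cf, truth, tissue = small_field
        dm = density_heatmap(segment_rf(rf, tissue))
        out = tmp_path / "heat.png"
        render_heatmap(dm, out)
        assert out.stat().st_size > 0


class TestGeneratorRecovery:
    def test_patch_count_and_areas_recovered_exactly(self, small_field):
        rf, cf, truth, tissue = small_field
        patches = segment_rf(rf, tissue)
        assert patches.count == truth.true_patch_count
        np.testing.assert_allclose(
            sorted(patches.patches["area_um2"]),
            sorted(truth.true_patch_areas_um2),
        )

    def test_rf_area_fraction_recovered(self, small_field):
        rf, cf, truth, tissue = small_field
        patches = segment_rf(rf, tissue)
        got = patches.total_area_um2 / (tissue.tissue_area_mm2 * 1e6)
        assert got == pytest.approx(truth.true_rf_area_fraction, abs=1e-9)
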