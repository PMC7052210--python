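"""Patch individualization and per-slice metrics for RF and CF/SHG signals.

The retinoid-fluorescence (RF) channel is thresholded and its connected
regions are individualized as "patches" -- a patch may be one droplet,
several droplets in one cell, or a cluster of droplet-laden cells; the
ambiguity is deliberate and the metrics never assume a per-cell resolution.
From the patch set and the collagen (CF/SHG) mask the module derives the
slice summary: percentage of tissue area covered by each signal, patch
density per mm², patch-size histogram, patch-to-collagen proximity, and the
100 x 100 µm gridded heat map of patch counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops

from .mosaic import ChannelImage, TissueMask

__all__ = [
    "PatchSet",
    "CollagenMask",
    "SliceMetrics",
    "DensityMap",
    "segment_rf",
    "segment_cf",
    "slice_metrics",
    "density_heatmap",
    "render_heatmap",
]

#: Connected regions smaller than this are treated as noise speckle.
DEFAULT_MIN_AREA_UM2 = 10.0
#: A patch is "near collagen" if its centroid is within this distance.
DEFAULT_PROXIMITY_RADIUS_UM = 20.0
#: Heat-map cell edge (µm).
DEFAULT_CELL_SIZE_UM = 100.0
#: Patch-size histogram bin edges in µm²; the last bin is open-ended so the
#: counts always sum to the patch count.
DEFAULT_SIZE_BINS_UM2 = (0.0, 25.0, 50.0, 100.0, 200.0, 400.0, 800.0, 1600.0,
                         3200.0, np.inf)

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass
class PatchSet:
    """Individualized RF patches on one slice.

    ``patches`` is a table with one row per patch: ``id``, ``area_um2``,
    ``centroid_x_um``, ``centroid_y_um`` and the pixel bounding box
    (``bbox_min_row``, ``bbox_min_col``, ``bbox_max_row``, ``bbox_max_col``,
    half-open).  ``label_image`` assigns each pixel its patch id (0 =
    background).
    """

    label_image: np.ndarray
    patches: pd.DataFrame
    tissue_area_mm2: float
    pixel_size_um: float

    @property
    def count(self) -> int:
        return len(self.patches)

    @property
    def total_area_um2(self) -> float:
        return float(self.patches["area_um2"].sum())


@dataclass
class CollagenMask:
    """Binary CF/SHG collagen mask with its area in mm²."""

    mask: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def cf_area_mm2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size_um**2 / 1e6


@dataclass
class SliceMetrics:
    """Per-slice summary of the RF / CF quantification.

    Percentages are referenced to the tissue-mask area (primary); the
    whole-frame-referenced values are also carried because the denominator
    convention changes the numbers.
    """

    rf_area_pct: float
    cf_area_pct: float
    rf_patch_density_per_mm2: float
    size_histogram: pd.DataFrame
    proximity: dict
    rf_area_pct_frame: float
    cf_area_pct_frame: float
    n_patches: int
    tissue_area_mm2: float

    def as_row(self) -> pd.DataFrame:
        """One-row summary table (histogram excluded)."""
        d = {
            "rf_area_pct": self.rf_area_pct,
            "cf_area_pct": self.cf_area_pct,
            "rf_patch_density_per_mm2": self.rf_patch_density_per_mm2,
            "n_patches": self.n_patches,
            "tissue_area_mm2": self.tissue_area_mm2,
            "rf_area_pct_frame": self.rf_area_pct_frame,
            "cf_area_pct_frame": self.cf_area_pct_frame,
            "fraction_patches_near_collagen": self.proximity[
                "fraction_patches_near_collagen"
            ],
            "median_nearest_distance_um": self.proximity[
                "median_nearest_distance_um"
            ],
        }
        return pd.DataFrame([d])


@dataclass
class DensityMap:
    """Gridded patch counts: number of patch centroids per square cell."""

    grid: np.ndarray
    cell_size_um: float = DEFAULT_CELL_SIZE_UM
    origin_um: tuple[float, float] = (0.0, 0.0)

    @property
    def total(self) -> int:
        return int(self.grid.sum())


def _binarize(
    image: ChannelImage,
    tissue: TissueMask,
    threshold: float | None,
    min_area_um2: float,
) -> np.ndarray:
    if image.shape != tissue.mask.shape:
        raise ValueError("image and tissue mask must be aligned")
    if tissue.is_empty:
        raise ValueError("tissue mask is empty")
    vals = image.pixels[tissue.mask]
    if threshold is None:
        if vals.max() == vals.min():
            # constant signal inside tissue: nothing to individualize
            threshold = vals.max()
        else:
            threshold = threshold_otsu(vals)
    binary = (image.pixels > threshold) & tissue.mask
    binary = ndimage.binary_fill_holes(binary)
    min_px = int(round(min_area_um2 / image.pixel_size_um**2))
    if min_px > 1:
        lab, n = ndimage.label(binary, structure=_EIGHT_CONNECTED)
        sizes = ndimage.sum_labels(binary, lab, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_px) + 1
        binary = np.isin(lab, keep)
    return binary


def segment_rf(
    rf: ChannelImage,
    tissue: TissueMask,
    threshold: float | None = None,
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
) -> PatchSet:
    """Individualize RF signal into patches.

    The RF channel is thresholded (automatic Otsu threshold over tissue
    pixels by default, or a fixed value), restricted to the tissue mask,
    hole-filled, cleaned of components below ``min_area_um2``, and labeled
    under 8-connectivity (diagonal contact merges regions).
    """
    binary = _binarize(rf, tissue, threshold, min_area_um2)
    label_image, n = ndimage.label(binary, structure=_EIGHT_CONNECTED)
    px = rf.pixel_size_um
    rows = []
    for prop in regionprops(label_image):
        cy, cx = prop.centroid
        rows.append(
            {
                "id": prop.label,
                "area_um2": prop.area * px**2,
                "centroid_x_um": (cx + 0.5) * px,
                "centroid_y_um": (cy + 0.5) * px,
                "bbox_min_row": prop.bbox[0],
                "bbox_min_col": prop.bbox[1],
                "bbox_max_row": prop.bbox[2],
                "bbox_max_col": prop.bbox[3],
            }
        )
    patches = pd.DataFrame(
        rows,
        columns=[
            "id", "area_um2", "centroid_x_um", "centroid_y_um",
            "bbox_min_row", "bbox_min_col", "bbox_max_row", "bbox_max_col",
        ],
    )
    return PatchSet(
        label_image=label_image,
        patches=patches,
        tissue_area_mm2=tissue.tissue_area_mm2,
        pixel_size_um=px,
    )


def segment_cf(
    cf: ChannelImage,
    tissue: TissueMask,
    threshold: float | None = None,
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
) -> CollagenMask:
    """Threshold the CF/SHG channel into a collagen mask (tissue-restricted)."""
    binary = _binarize(cf, tissue, threshold, min_area_um2)
    return CollagenMask(binary, cf.pixel_size_um)


def _nearest_collagen_distances(
    patches: PatchSet, collagen: CollagenMask
) -> np.ndarray:
    """Distance (µm) from each patch centroid to the nearest collagen pixel."""
    if patches.count == 0:
        return np.empty(0)
    if not collagen.mask.any():
        return np.full(patches.count, np.inf)
    # EDT of the complement: 0 on collagen, distance to it elsewhere
    dist_px = ndimage.distance_transform_edt(~collagen.mask)
    px = patches.pixel_size_um
    h, w = collagen.mask.shape
    rows = np.clip(
        (patches.patches["centroid_y_um"].to_numpy() / px - 0.5).round().astype(int),
        0, h - 1,
    )
    cols = np.clip(
        (patches.patches["centroid_x_um"].to_numpy() / px - 0.5).round().astype(int),
        0, w - 1,
    )
    return dist_px[rows, cols] * px


def slice_metrics(
    patches: PatchSet,
    collagen: CollagenMask,
    tissue: TissueMask,
    size_bins_um2=DEFAULT_SIZE_BINS_UM2,
    proximity_radius_um: float = DEFAULT_PROXIMITY_RADIUS_UM,
) -> SliceMetrics:
    """Compute the per-slice summary.

    rf_area_pct = 100 * (sum of patch areas) / tissue area;
    cf_area_pct analogously from the collagen mask;
    density = patch count / tissue area (mm²);
    the size histogram bins patch areas (µm²) over ``size_bins_um2``;
    proximity uses the centroid-to-nearest-collagen-pixel distance.
    """
    if patches.pixel_size_um != collagen.pixel_size_um:
        raise ValueError("pixel sizes of patches and collagen differ")
    tissue_mm2 = tissue.tissue_area_mm2
    if tissue_mm2 <= 0:
        raise ValueError("tissue area is zero")
    frame_mm2 = tissue.mask.size * tissue.pixel_size_um**2 / 1e6
    rf_mm2 = patches.total_area_um2 / 1e6
    cf_mm2 = collagen.cf_area_mm2

    edges = np.asarray(size_bins_um2, dtype=float)
    counts, _ = np.histogram(patches.patches["area_um2"].to_numpy(), bins=edges)
    hist = pd.DataFrame(
        {"bin_low_um2": edges[:-1], "bin_high_um2": edges[1:], "count": counts}
    )

    dists = _nearest_collagen_distances(patches, collagen)
    if len(dists) == 0:
        proximity = {
            "fraction_patches_near_collagen": np.nan,
            "median_nearest_distance_um": np.nan,
            "radius_um": proximity_radius_um,
        }
    else:
        proximity = {
            "fraction_patches_near_collagen": float(
                np.mean(dists <= proximity_radius_um)
            ),
            "median_nearest_distance_um": float(np.median(dists)),
            "radius_um": proximity_radius_um,
        }

    return SliceMetrics(
        rf_area_pct=100.0 * rf_mm2 / tissue_mm2,
        cf_area_pct=100.0 * cf_mm2 / tissue_mm2,
        rf_patch_density_per_mm2=patches.count / tissue_mm2,
        size_histogram=hist,
        proximity=proximity,
        rf_area_pct_frame=100.0 * rf_mm2 / frame_mm2,
        cf_area_pct_frame=100.0 * cf_mm2 / frame_mm2,
        n_patches=patches.count,
        tissue_area_mm2=tissue_mm2,
    )


def density_heatmap(
    patches: PatchSet, cell_size_um: float = DEFAULT_CELL_SIZE_UM
) -> DensityMap:
    """Grid the field into ``cell_size_um`` squares and count patch centroids.

    Each patch is counted exactly once, in the cell containing its centroid
    (floor convention: a centroid exactly on an interior boundary belongs to
    the higher-index cell).  Partial cells at the right/bottom edges are kept,
    so the grid tiles the full image and the counts sum to the patch count.
    """
    if cell_size_um <= 0:
        raise ValueError("cell_size_um must be positive")
    h, w = patches.label_image.shape
    px = patches.pixel_size_um
    n_rows = max(1, int(np.ceil(h * px / cell_size_um)))
    n_cols = max(1, int(np.ceil(w * px / cell_size_um)))
    grid = np.zeros((n_rows, n_cols), dtype=int)
    if patches.count:
        gx = np.floor(
            patches.patches["centroid_x_um"].to_numpy() / cell_size_um
        ).astype(int)
        gy = np.floor(
            patches.patches["centroid_y_um"].to_numpy() / cell_size_um
        ).astype(int)
        gx = np.clip(gx, 0, n_cols - 1)
        gy = np.clip(gy, 0, n_rows - 1)
        np.add.at(grid, (gy, gx), 1)
    return DensityMap(grid=grid, cell_size_um=cell_size_um)


def render_heatmap(density: DensityMap, path) -> None:
    """Render the density map to PNG with a count color scale."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    n_rows, n_cols = density.grid.shape
    im = ax.imshow(
        density.grid,
        cmap="inferno",
        origin="upper",
        extent=(
            0, n_cols * density.cell_size_um, n_rows * density.cell_size_um, 0,
        ),
    )
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    cbar = fig.colorbar(im, ax=ax)
    cbar.set_label(
        f"RF patches per {density.cell_size_um:g} × {density.cell_size_um:g} µm square"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
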