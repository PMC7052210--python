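"""Image containers, tiled-acquisition assembly, z-projection and tissue masking.

Whole liver slices are acquired as overlapping 512x512 tiles (10 % overlap by
default) and as z-stacks at 3 µm steps.  This module reassembles those
acquisitions into single planes and delimits the tissue region whose area is
the denominator of every area-percentage metric downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "ChannelImage",
    "TileGrid",
    "TissueMask",
    "split_into_tiles",
    "assemble_mosaic",
    "project_stack",
    "tissue_mask",
    "read_channel_image",
    "write_channel_image",
    "write_mask",
]

#: Default acquisition tile size in pixels.
DEFAULT_TILE_SIZE_PX = 512
#: Default fractional overlap between adjacent tiles.
DEFAULT_OVERLAP_FRACTION = 0.10


@dataclass
class ChannelImage:
    """One 2D intensity plane with physical pixel size.

    Parameters
    ----------
    pixels
        Non-negative 2D intensity array.  Origin (0, 0) is the top-left
        pixel; x runs rightward (columns), y downward (rows).
    pixel_size_um
        Physical edge length of one pixel, in µm.
    channel
        Channel label: ``"RF"`` (retinoid fluorescence), ``"CF_SHG"``
        (collagen second-harmonic) or ``"derived"``.

    Physical coordinates refer to pixel centers:
    ``x_um = (col + 0.5) * pixel_size_um``.
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel: str = "derived"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the field in µm."""
        h, w = self.pixels.shape
        return (w * self.pixel_size_um, h * self.pixel_size_um)


@dataclass
class TileGrid:
    """A rectangular grid of overlapping tiles cut from (or acquired as) one plane."""

    tiles: dict[tuple[int, int], np.ndarray]
    tile_size_px: int
    overlap_fraction: float
    pixel_size_um: float
    row_offsets: list[int]
    col_offsets: list[int]
    channel: str = "derived"

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must be in [0, 1)")
        shapes = {t.shape for t in self.tiles.values()}
        if len(shapes) > 1:
            raise ValueError("all tiles must share the same shape")

    @property
    def n_rows(self) -> int:
        return len(self.row_offsets)

    @property
    def n_cols(self) -> int:
        return len(self.col_offsets)

    @property
    def mosaic_shape(self) -> tuple[int, int]:
        return (
            self.row_offsets[-1] + self.tile_size_px,
            self.col_offsets[-1] + self.tile_size_px,
        )


@dataclass
class TissueMask:
    """Binary delimitation of the slice; its area is the metric denominator.

    ``tissue_area_mm2`` is exactly ``mask.sum() * pixel_size_um**2 / 1e6``.
    """

    mask: np.ndarray
    pixel_size_um: float
    is_empty: bool = field(default=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        self.is_empty = bool(not self.mask.any())

    @property
    def tissue_area_mm2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size_um**2 / 1e6

    @classmethod
    def full(cls, shape: tuple[int, int], pixel_size_um: float) -> "TissueMask":
        """Mask covering the whole frame (synthetic fields with no margin)."""
        return cls(np.ones(shape, dtype=bool), pixel_size_um)


def _tile_offsets(extent: int, tile: int, stride: int) -> list[int]:
    """Offsets of tile origins covering ``[0, extent)``; the last tile is
    clamped to the image edge when the stride does not divide evenly."""
    offsets = list(range(0, extent - tile + 1, stride))
    if offsets[-1] + tile < extent:
        offsets.append(extent - tile)
    return offsets


def split_into_tiles(
    image: ChannelImage,
    tile_size_px: int = DEFAULT_TILE_SIZE_PX,
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
) -> TileGrid:
    """Cut a plane into overlapping tiles (inverse of the acquisition tiling).

    Adjacent tiles share ``round(tile_size_px * overlap_fraction)`` pixels;
    edge tiles are clamped so the grid always covers the full image.
    """
    if not (0 <= overlap_fraction < 1):
        raise ValueError("overlap_fraction must be in [0, 1)")
    h, w = image.shape
    if h < tile_size_px or w < tile_size_px:
        raise ValueError(
            f"image {h}x{w} is smaller than one {tile_size_px}px tile"
        )
    overlap_px = int(round(tile_size_px * overlap_fraction))
    stride = tile_size_px - overlap_px
    if stride < 1:
        raise ValueError("overlap leaves a non-positive stride")
    row_offsets = _tile_offsets(h, tile_size_px, stride)
    col_offsets = _tile_offsets(w, tile_size_px, stride)
    tiles = {
        (r, c): image.pixels[
            ro : ro + tile_size_px, co : co + tile_size_px
        ].copy()
        for r, ro in enumerate(row_offsets)
        for c, co in enumerate(col_offsets)
    }
    return TileGrid(
        tiles=tiles,
        tile_size_px=tile_size_px,
        overlap_fraction=overlap_fraction,
        pixel_size_um=image.pixel_size_um,
        row_offsets=row_offsets,
        col_offsets=col_offsets,
        channel=image.channel,
    )


def assemble_mosaic(grid: TileGrid) -> ChannelImage:
    """Assemble a tile grid into one plane, averaging overlap regions.

    Where every contributing tile agrees, the output is bit-identical to the
    contribution (so a noise-free split -> assemble round trip reproduces the
    original exactly); where tiles disagree, the unweighted mean is used.
    """
    expected = {
        (r, c) for r in range(grid.n_rows) for c in range(grid.n_cols)
    }
    missing = expected - set(grid.tiles)
    if missing:
        raise ValueError(f"missing grid positions: {sorted(missing)}")

    shape = grid.mosaic_shape
    total = np.zeros(shape, dtype=float)
    count = np.zeros(shape, dtype=int)
    lo = np.full(shape, np.inf)
    hi = np.full(shape, -np.inf)
    t = grid.tile_size_px
    for (r, c), tile in grid.tiles.items():
        ro, co = grid.row_offsets[r], grid.col_offsets[c]
        sl = (slice(ro, ro + t), slice(co, co + t))
        total[sl] += tile
        count[sl] += 1
        np.minimum(lo[sl], tile, out=lo[sl])
        np.maximum(hi[sl], tile, out=hi[sl])
    if np.any(count == 0):
        raise ValueError("tile grid does not cover the mosaic rectangle")
    # min == max means all contributions agree: take the exact value, not
    # sum/count (3a/3 is not bit-exact in floating point).
    mosaic = np.where(lo == hi, lo, total / count)
    return ChannelImage(mosaic, grid.pixel_size_um, grid.channel)


def project_stack(planes: list[ChannelImage]) -> ChannelImage:
    """Maximum-intensity projection of a z-stack.

    The acquisition averages nothing along z; MIP preserves bright droplets
    that appear in a single optical section.
    """
    if len(planes) == 0:
        raise ValueError("need at least one plane")
    shape = planes[0].shape
    px = planes[0].pixel_size_um
    for p in planes[1:]:
        if p.shape != shape:
            raise ValueError("all planes must share the same shape")
        if p.pixel_size_um != px:
            raise ValueError("all planes must share the same pixel size")
    projected = np.maximum.reduce([p.pixels for p in planes])
    return ChannelImage(projected, px, planes[0].channel)


def tissue_mask(
    rf: ChannelImage,
    cf: ChannelImage,
    smooth_sigma_px: float = 1.0,
    min_area_um2: float = 100.0,
) -> TissueMask:
    """Delimit the tissue slice from the summed RF + CF/SHG channels.

    An automatic (Otsu) global threshold is applied to the Gaussian-smoothed
    sum image, holes are filled, and connected components smaller than
    ``min_area_um2`` are dropped.  An all-zero input yields an empty mask
    (``is_empty``) with a warning rather than an error.
    """
    if rf.shape != cf.shape:
        raise ValueError("RF and CF images must be aligned")
    if rf.pixel_size_um != cf.pixel_size_um:
        raise ValueError("RF and CF pixel sizes differ")
    px = rf.pixel_size_um
    summed = rf.pixels + cf.pixels
    if smooth_sigma_px > 0:
        summed = ndimage.gaussian_filter(summed, sigma=smooth_sigma_px)
    if summed.max() == summed.min():
        if summed.max() == 0:
            warnings.warn("all-zero input: empty tissue mask", stacklevel=2)
            return TissueMask(np.zeros(rf.shape, dtype=bool), px)
        return TissueMask(np.ones(rf.shape, dtype=bool), px)
    thr = threshold_otsu(summed)
    mask = summed > thr
    mask = ndimage.binary_fill_holes(mask)
    min_px = max(1, int(round(min_area_um2 / px**2)))
    if min_px > 1:
        lab, n = ndimage.label(mask, structure=np.ones((3, 3)))
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
        mask = np.isin(lab, np.flatnonzero(sizes >= min_px) + 1)
    if not mask.any():
        warnings.warn("tissue mask is empty after filtering", stacklevel=2)
    return TissueMask(mask, px)


# ---------------------------------------------------------------------------
# TIFF I/O.  Pixel size is carried in the X/Y resolution tags (pixels per µm,
# RESUNIT NONE with an ImageJ-style unit field) so round trips need no sidecar.


def write_channel_image(path, image: ChannelImage) -> None:
    """Write one plane (or use a list of planes for multi-page) as TIFF."""
    res = 1.0 / image.pixel_size_um
    tifffile.imwrite(
        str(path),
        image.pixels.astype(np.float32),
        resolution=(res, res),
        metadata={"unit": "um", "channel": image.channel},
    )


def read_channel_image(
    path, pixel_size_um: float | None = None, channel: str | None = None
) -> ChannelImage:
    """Read a single-page TIFF; pixel size from metadata unless overridden."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        pixels = page.asarray()
        if pixel_size_um is None:
            tag = page.tags.get("XResolution")
            if tag is None:
                raise ValueError(
                    "no resolution metadata in TIFF; pass pixel_size_um"
                )
            num, den = tag.value
            pixel_size_um = den / num
        if channel is None:
            channel = "derived"
            meta = tif.shaped_metadata or tif.imagej_metadata or ()
            if isinstance(meta, dict):
                meta = (meta,)
            for d in meta:
                if isinstance(d, dict) and "channel" in d:
                    channel = str(d["channel"])
    return ChannelImage(np.asarray(pixels, dtype=float), pixel_size_um, channel)


def write_mask(path, mask: TissueMask) -> None:
    """Write a binary mask as 8-bit TIFF (0 / 255)."""
    res = 1.0 / mask.pixel_size_um
    tifffile.imwrite(
        str(path),
        (mask.mask.astype(np.uint8) * 255),
        resolution=(res, res),
        metadata={"unit": "um"},
    )
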