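"""Tile handling and tissue isolation.

Whole-section rasters are split into fixed-size tiles on a row-major grid
(edge tiles are kept at their natural size), and a simple brightness /
saturation rule separates analysable tissue from the bright empty background
of a scanned slide, with small connected specks removed as debris.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.colors import rgb_to_hsv
from skimage import morphology


@dataclass(frozen=True)
class TileImage:
    """One 8-bit RGB tile with provenance labels."""

    pixel_raster: np.ndarray
    case_id: str = ""
    stain_set: str = ""
    tile_index: int = 0
    row: int = 0
    col: int = 0
    is_edge: bool = False

    def __post_init__(self) -> None:
        raster = np.asarray(self.pixel_raster)
        if raster.ndim != 3 or raster.shape[2] != 3:
            raise ValueError("tile must be H x W x 3")
        if raster.dtype != np.uint8:
            raise ValueError("tile must be 8-bit per channel")

    @property
    def width(self) -> int:
        return self.pixel_raster.shape[1]

    @property
    def height(self) -> int:
        return self.pixel_raster.shape[0]


@dataclass(frozen=True)
class TissueMask:
    """Boolean analysable-tissue mask for one tile."""

    mask_raster: np.ndarray
    tissue_pixel_count: int = field(default=-1)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask_raster)
        if mask.dtype != bool or mask.ndim != 2:
            raise ValueError("mask must be 2-D boolean")
        n = int(mask.sum())
        if self.tissue_pixel_count < 0:
            object.__setattr__(self, "tissue_pixel_count", n)
        elif self.tissue_pixel_count != n:
            raise ValueError("tissue_pixel_count disagrees with mask")

    @property
    def tissue_fraction(self) -> float:
        return self.tissue_pixel_count / self.mask_raster.size


def split_tiles(
    image: np.ndarray,
    tile_size: int,
    case_id: str = "",
    stain_set: str = "",
) -> list[TileImage]:
    """Split an RGB raster into row-major ``tile_size`` tiles.

    Edge tiles smaller than ``tile_size`` are retained and flagged;
    concatenating all tiles on the grid reconstructs the image exactly.
    """
    if tile_size < 32:
        raise ValueError("tile_size must be >= 32")
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    h, w = image.shape[:2]
    tiles = []
    index = 0
    for r, y in enumerate(range(0, h, tile_size)):
        for c, x in enumerate(range(0, w, tile_size)):
            patch = image[y : y + tile_size, x : x + tile_size]
            tiles.append(
                TileImage(
                    pixel_raster=np.ascontiguousarray(patch),
                    case_id=case_id,
                    stain_set=stain_set,
                    tile_index=index,
                    row=r,
                    col=c,
                    is_edge=patch.shape[0] < tile_size or patch.shape[1] < tile_size,
                )
            )
            index += 1
    return tiles


def reassemble(tiles: list[TileImage]) -> np.ndarray:
    """Inverse of :func:`split_tiles` for a complete tile set."""
    n_rows = max(t.row for t in tiles) + 1
    rows = []
    for r in range(n_rows):
        row_tiles = sorted((t for t in tiles if t.row == r), key=lambda t: t.col)
        rows.append(np.concatenate([t.pixel_raster for t in row_tiles], axis=1))
    return np.concatenate(rows, axis=0)


def compute_tissue_mask(
    tile: TileImage,
    brightness_cutoff: float = 0.92,
    min_object_px: int = 64,
    saturation_cutoff: float = 0.08,
) -> TissueMask:
    """Isolate tissue from bright empty background and discard debris.

    A pixel is background when its HSB brightness is at least
    ``brightness_cutoff`` *and* its saturation is below ``saturation_cutoff``
    (near-white, as empty slide regions are).  Connected foreground
    components smaller than ``min_object_px`` are removed as debris.
    """
    if not 0.0 < brightness_cutoff < 1.0:
        raise ValueError("brightness_cutoff must be in (0, 1)")
    if min_object_px < 0:
        raise ValueError("min_object_px must be >= 0")
    hsv = rgb_to_hsv(tile.pixel_raster.astype(float) / 255.0)
    background = (hsv[..., 2] >= brightness_cutoff) & (hsv[..., 1] < saturation_cutoff)
    mask = ~background
    if min_object_px > 0:
        # remove foreground components of fewer than min_object_px pixels
        mask = morphology.remove_small_objects(mask, max_size=min_object_px - 1)
    return TissueMask(mask_raster=mask)


def filter_tiles(
    tiles_with_masks: list[tuple[TileImage, TissueMask]],
    min_tissue_fraction: float,
) -> tuple[list[tuple[TileImage, TissueMask]], list[bool]]:
    """Retain tiles whose tissue fraction is at least the cutoff.

    Returns the retained (tile, mask) pairs and the per-tile retention
    decision in input order.
    """
    if not 0.0 <= min_tissue_fraction <= 1.0:
        raise ValueError("min_tissue_fraction must be in [0, 1]")
    decisions = [m.tissue_fraction >= min_tissue_fraction for _, m in tiles_with_masks]
    retained = [pair for pair, keep in zip(tiles_with_masks, decisions) if keep]
    return retained, decisions
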