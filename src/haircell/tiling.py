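"""Tiled processing of large micrographs.

Detection runs on small square crops (256 px by default) with 10% overlap
along every edge so each cell is fully contained in at least one tile.
Edge tiles are shifted inward (never padded), so all tiles lie fully inside
the image and their union covers every pixel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import InputError

DEFAULT_TILE_SIZE = 256
DEFAULT_OVERLAP = 0.10

# Blank-region skipping defaults (optional speed-up, off by default).
DEFAULT_BLANK_MIN_INTENSITY = 0.05
DEFAULT_BLANK_MIN_FRACTION = 0.01


@dataclass(frozen=True)
class TileSpec:
    """One crop: global origin (0-based, row/col), size, and running index."""

    origin_row: int
    origin_col: int
    height: int
    width: int
    index: int

    def extract(self, pixels: np.ndarray) -> np.ndarray:
        """Crop this tile out of a (C, H, W) or (H, W) array."""
        r, c = self.origin_row, self.origin_col
        return pixels[..., r : r + self.height, c : c + self.width]


def _axis_origins(dim: int, tile: int, stride: int) -> list:
    if dim <= tile:
        return [0]
    origins = list(range(0, dim - tile, stride))
    last = dim - tile
    if origins[-1] != last:
        origins.append(last)
    return origins


def plan_tiles(
    image_height: int,
    image_width: int,
    tile_size: int = DEFAULT_TILE_SIZE,
    overlap_fraction: float = DEFAULT_OVERLAP,
) -> list:
    """Row-major list of tiles covering an image.

    stride = floor(tile_size * (1 - overlap_fraction)); the final tile on
    each axis is clamped to the image edge. An image smaller than the tile
    yields a single tile of the image's own size.
    """
    if image_height <= 0 or image_width <= 0:
        raise InputError(f"image dimensions must be positive; got {image_height}x{image_width}")
    if tile_size < 1:
        raise InputError(f"tile_size must be >= 1; got {tile_size}")
    if not (0 <= overlap_fraction < 1):
        raise InputError(f"overlap_fraction must be in [0, 1); got {overlap_fraction}")

    stride = max(1, int(np.floor(tile_size * (1.0 - overlap_fraction))))
    rows = _axis_origins(image_height, tile_size, stride)
    cols = _axis_origins(image_width, tile_size, stride)
    h = min(tile_size, image_height)
    w = min(tile_size, image_width)
    tiles = []
    for r in rows:
        for c in cols:
            tiles.append(TileSpec(r, c, h, w, index=len(tiles)))
    return tiles


def is_blank(
    tile_pixels: np.ndarray,
    min_intensity: float = DEFAULT_BLANK_MIN_INTENSITY,
    min_fraction: float = DEFAULT_BLANK_MIN_FRACTION,
) -> bool:
    """True iff the fraction of pixels (any channel) above *min_intensity*
    falls below *min_fraction*."""
    if not (0 <= min_intensity <= 1 and 0 <= min_fraction <= 1):
        raise InputError("blank-skip thresholds must lie in [0, 1]")
    px = np.asarray(tile_pixels)
    if px.ndim == 2:
        px = px[None]
    supra = (px > min_intensity).any(axis=0)
    return supra.mean() < min_fraction


def to_global(detection, tile: TileSpec):
    """Translate a tile-local detection into global image coordinates.

    Boxes reaching past the tile extent are clipped with a warning; the
    tile index is recorded for provenance.
    """
    r0, c0, r1, c1 = detection.box
    if r0 < 0 or c0 < 0 or r1 > tile.height or c1 > tile.width:
        warnings.warn(
            f"detection box {detection.box} exceeds tile {tile.index} extent; clipping",
            stacklevel=2,
        )
        r0, r1 = np.clip([r0, r1], 0, tile.height)
        c0, c1 = np.clip([c0, c1], 0, tile.width)
    return replace(
        detection,
        box=(
            r0 + tile.origin_row,
            c0 + tile.origin_col,
            r1 + tile.origin_row,
            c1 + tile.origin_col,
        ),
        tile_index=tile.index,
    )


def to_local(detection, tile: TileSpec):
    """Inverse of :func:`to_global`."""
    r0, c0, r1, c1 = detection.box
    return replace(
        detection,
        box=(
            r0 - tile.origin_row,
            c0 - tile.origin_col,
            r1 - tile.origin_row,
            c1 - tile.origin_col,
        ),
        tile_index=None,
    )
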