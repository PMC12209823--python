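"""Foreground segmentation and tile-grid construction for slide images.

A slide image is converted to a grid of non-overlapping square tiles
(default 256 px).  Foreground is found by Otsu thresholding of the mean
luminance — tissue is *darker* than the bright slide background, so
foreground pixels are those strictly below the threshold — and tiles whose
foreground occupancy falls below a fixed threshold (default 0.1) are
flagged as discarded.  Filtering flags tiles rather than deleting rows, so
grid geometry stays intact for heatmaps and overlays.

Coordinates are 0-based (row, col) with the pixel origin top-left and
half-open tile footprints [x0, x0 + tile_size).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

DEFAULT_TILE_SIZE = 256
DEFAULT_MIN_OCCUPANCY = 0.1

#: per-channel (mean, sd) on the [0, 1] scale for ImageNet-style baselines
IMAGENET_NORM = ((0.485, 0.229), (0.456, 0.224), (0.406, 0.225))

GRID_COLUMNS = ["row", "col", "x0", "y0", "occupancy", "kept"]


@dataclass
class TileGrid:
    """Non-overlapping tile lattice of one slide, with occupancy flags."""

    slide_id: str
    tile_size: int
    tiles: pd.DataFrame  # columns: row, col, x0, y0, occupancy, kept

    @property
    def n_rows(self) -> int:
        return 0 if len(self.tiles) == 0 else int(self.tiles["row"].max()) + 1

    @property
    def n_cols(self) -> int:
        return 0 if len(self.tiles) == 0 else int(self.tiles["col"].max()) + 1

    def kept(self) -> pd.DataFrame:
        return self.tiles[self.tiles["kept"]]

    def kept_coords(self) -> np.ndarray:
        return self.kept()[["row", "col"]].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        df = self.tiles.copy()
        df.insert(0, "slide_id", self.slide_id)
        df.insert(1, "tile_size", self.tile_size)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, tile_size: int | None = None) -> "TileGrid":
        df = pd.read_csv(path)
        slide_id = str(df["slide_id"].iloc[0]) if len(df) else "slide"
        if tile_size is None:
            tile_size = int(df["tile_size"].iloc[0]) if len(df) else DEFAULT_TILE_SIZE
        return cls(slide_id=slide_id, tile_size=tile_size, tiles=df[GRID_COLUMNS])


def luminance(image: np.ndarray) -> np.ndarray:
    """Mean of the three colour channels per pixel (float, same spatial dims)."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB image (H, W, 3), got shape {image.shape}")
    return image.astype(np.float64).mean(axis=2)


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu's threshold from a 256-bin intensity histogram.

    Returns the integer t in [0, 255] maximizing the between-class variance
    of the split {0..t} vs {t+1..255}; ties resolved to the smallest
    qualifying t.  A single-populated-bin histogram is degenerate: that bin
    index is returned with a warning.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError("histogram must have exactly 256 bins")
    if hist.sum() <= 0:
        raise ValueError("histogram is empty (all-zero counts)")
    nonzero = np.flatnonzero(hist)
    if len(nonzero) == 1:
        warnings.warn("single-valued histogram; Otsu threshold is degenerate")
        return int(nonzero[0])

    p = hist / hist.sum()
    bins = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(p)  # weight of class {0..t}
    mu = np.cumsum(p * bins)
    mu_total = mu[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu / w0
        mu1 = (mu_total - mu) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between = np.nan_to_num(between, nan=-1.0)
    return int(np.argmax(between))  # argmax takes the first (smallest) maximizer


def image_histogram(gray: np.ndarray) -> np.ndarray:
    """256-bin histogram of a luminance image (values clipped to [0, 255])."""
    vals = np.clip(np.asarray(gray), 0, 255).astype(np.int64)
    return np.bincount(vals.ravel(), minlength=256)[:256]


def foreground_mask(gray: np.ndarray, threshold: int) -> np.ndarray:
    """Tissue mask: pixels with luminance strictly below the threshold."""
    return np.asarray(gray) < threshold


def tile_grid(
    width: int,
    height: int,
    tile_size: int = DEFAULT_TILE_SIZE,
    slide_id: str = "slide",
) -> TileGrid:
    """Full lattice of floor(h/ts) x floor(w/ts) tiles; remainders discarded.

    All tiles start with occupancy 1 and kept=True; :func:`occupancy_filter`
    fills in measured occupancies.
    """
    if width <= 0 or height <= 0:
        raise ValueError("image dimensions must be positive")
    n_rows, n_cols = height // tile_size, width // tile_size
    if n_rows == 0 or n_cols == 0:
        logger.warning(
            "tile_size %d exceeds image dims (%d, %d); empty grid", tile_size, width, height
        )
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    df = pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "x0": cols.ravel() * tile_size,
            "y0": rows.ravel() * tile_size,
            "occupancy": 1.0,
            "kept": True,
        }
    )
    return TileGrid(slide_id=slide_id, tile_size=tile_size, tiles=df)


def occupancy_filter(
    grid: TileGrid, mask: np.ndarray, min_occupancy: float = DEFAULT_MIN_OCCUPANCY
) -> TileGrid:
    """Compute per-tile foreground occupancy and flag tiles below threshold.

    A tile is kept iff its foreground-pixel fraction is >= ``min_occupancy``
    (tiles strictly below the threshold are discarded).  The tile count is
    unchanged: filtering is flagging, not deletion.
    """
    if not (0.0 <= min_occupancy <= 1.0):
        raise ValueError("min_occupancy must lie in [0, 1]")
    mask = np.asarray(mask, dtype=bool)
    ts = grid.tile_size
    n_rows, n_cols = grid.n_rows, grid.n_cols
    if mask.shape[0] < n_rows * ts or mask.shape[1] < n_cols * ts:
        raise ValueError("mask does not cover the tile grid")
    if len(grid.tiles) == 0:
        return replace(grid, tiles=grid.tiles.copy())
    block = mask[: n_rows * ts, : n_cols * ts].reshape(n_rows, ts, n_cols, ts)
    occ = block.mean(axis=(1, 3))
    tiles = grid.tiles.copy()
    tiles["occupancy"] = occ[tiles["row"].to_numpy(), tiles["col"].to_numpy()]
    tiles["kept"] = tiles["occupancy"] >= min_occupancy
    return replace(grid, tiles=tiles)


def segment_image(
    image: np.ndarray,
    tile_size: int = DEFAULT_TILE_SIZE,
    min_occupancy: float = DEFAULT_MIN_OCCUPANCY,
    slide_id: str = "slide",
    otsu_downsample: int = 1,
) -> tuple[TileGrid, np.ndarray]:
    """Luminance -> Otsu -> foreground mask -> occupancy-filtered grid.

    ``otsu_downsample`` > 1 estimates the Otsu threshold from a strided
    thumbnail of the luminance image (useful for gigapixel inputs); the
    mask itself is always computed at full resolution.
    """
    if otsu_downsample < 1:
        raise ValueError("otsu_downsample must be >= 1")
    gray = luminance(image)
    thumb = gray[::otsu_downsample, ::otsu_downsample]
    thr = otsu_threshold(image_histogram(thumb))
    mask = foreground_mask(gray, thr)
    grid = tile_grid(image.shape[1], image.shape[0], tile_size, slide_id=slide_id)
    return occupancy_filter(grid, mask, min_occupancy), mask


def crop_tile(image: np.ndarray, grid: TileGrid, row: int, col: int) -> np.ndarray:
    ts = grid.tile_size
    return np.asarray(image)[row * ts : (row + 1) * ts, col * ts : (col + 1) * ts]


def extract_tiles(
    image: np.ndarray,
    grid: TileGrid,
    out_dir: str | Path,
    kept_only: bool = True,
) -> list[Path]:
    """Write one lossless PNG per (kept) tile, named ``<slide>_<row>_<col>.png``."""
    image = np.asarray(image)
    ts = grid.tile_size
    if image.shape[0] < grid.n_rows * ts or image.shape[1] < grid.n_cols * ts:
        raise ValueError("image does not cover the tile grid")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = grid.kept() if kept_only else grid.tiles
    paths = []
    for _, t in rows.iterrows():
        tile = crop_tile(image, grid, int(t["row"]), int(t["col"]))
        path = out_dir / f"{grid.slide_id}_{int(t['row'])}_{int(t['col'])}.png"
        try:
            Image.fromarray(tile).save(path)
        except OSError as exc:  # pragma: no cover - disk failures
            raise OSError(f"failed writing tile {path}: {exc}") from exc
        paths.append(path)
    return paths


def center_crop_transform(
    tile: np.ndarray,
    crop: int = 224,
    normalize: tuple[tuple[float, float], ...] = IMAGENET_NORM,
) -> np.ndarray:
    """Center-crop to ``crop`` px and normalize channels on the [0, 1] scale.

    The preprocessing contract of ImageNet-pretrained baseline encoders;
    returns float32 (crop, crop, 3).
    """
    tile = np.asarray(tile)
    h, w = tile.shape[:2]
    if crop > min(h, w):
        raise ValueError(f"crop {crop} exceeds tile size {(h, w)}")
    y0, x0 = (h - crop) // 2, (w - crop) // 2
    out = tile[y0 : y0 + crop, x0 : x0 + crop].astype(np.float32) / 255.0
    for c, (mean, sd) in enumerate(normalize):
        out[:, :, c] = (out[:, :, c] - mean) / sd
    return out
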