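"""Tile embeddings: containers, the pluggable encoder interface, and persistence.

Real pathology foundation models (ViT-scale tile encoders) are external,
GPU-bound components.  This module fixes the *contract* they must satisfy —
one embedding row per kept tile, aligned with grid coordinates — and ships a
deterministic mock encoder so that every downstream stage can be exercised
without them.  Encoders are frozen by construction: nothing in this package
ever updates encoder parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import EmbeddingIOError

_MAGIC = b"WSEM"
_VERSION = 1


@dataclass
class TileEmbeddingMatrix:
    """Bag of tile embeddings for one slide.

    ``matrix`` has one float32 row per kept tile, in row-major scan order
    over the tile grid; ``coords`` holds the aligned ``(row, col)`` grid
    coordinates.
    """

    slide_id: str
    encoder_name: str
    matrix: np.ndarray
    coords: np.ndarray  # (n_tiles, 2) int array of (row, col)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float32)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        self.validate()

    @property
    def n_tiles(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def validate(self) -> None:
        if self.matrix.ndim != 2:
            raise EmbeddingIOError("embedding matrix must be 2-D")
        if self.matrix.shape[0] == 0:
            raise EmbeddingIOError(
                f"slide {self.slide_id!r} has no foreground tiles"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise EmbeddingIOError(
                f"non-finite values in embeddings for slide {self.slide_id!r}"
            )
        if self.coords.shape != (self.matrix.shape[0], 2):
            raise EmbeddingIOError(
                f"coords shape {self.coords.shape} does not match "
                f"{self.matrix.shape[0]} embedding rows"
            )
        uniq = {tuple(rc) for rc in self.coords.tolist()}
        if len(uniq) != self.coords.shape[0]:
            raise EmbeddingIOError("duplicate tile coordinates in bag")


@dataclass
class EncoderSpec:
    """Contract for a tile encoder.

    ``fn`` maps a uint8 RGB tile (H, W, 3) to a 1-D float vector of length
    ``embed_dim``.  ``crop`` optionally center-crops tiles to a square of
    that many pixels first, and ``normalize`` holds per-channel (mean, sd)
    pairs applied on the [0, 1] scale — the transform contract used by
    ImageNet-pretrained baselines (224 px crop, ImageNet statistics).
    """

    name: str
    embed_dim: int
    fn: Callable[[np.ndarray], np.ndarray]
    tile_size: int = 256
    crop: int | None = None
    normalize: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.embed_dim < 2:
            raise ValueError("embed_dim must be >= 2")


# ---------------------------------------------------------------------------
# Mock encoder
# ---------------------------------------------------------------------------

_N_HARMONICS = 4  # sin/cos pairs per channel in the feature summary


def mock_tile_features(tile: np.ndarray) -> np.ndarray:
    """Deterministic, Lipschitz summary features of an RGB tile.

    Per channel: mean and standard deviation of intensities (on [0, 1]),
    plus the spatial means of sin(k pi x) and cos(k pi x) for k = 1..4 —
    smooth random-Fourier-style moments, so small pixel perturbations give
    small feature changes.  3 channels x (2 + 8) = 30 features.
    """
    tile = np.asarray(tile)
    if tile.ndim != 3 or tile.shape[2] != 3:
        raise ValueError("expected an RGB tile of shape (H, W, 3)")
    x = tile.astype(np.float64) / 255.0
    feats = []
    for c in range(3):
        ch = x[:, :, c]
        feats.append(ch.mean())
        feats.append(ch.std())
        for k in range(1, _N_HARMONICS + 1):
            feats.append(np.sin(k * np.pi * ch).mean())
            feats.append(np.cos(k * np.pi * ch).mean())
    return np.asarray(feats)


def mock_encode(tile: np.ndarray, d: int, seed: int = 0) -> np.ndarray:
    """Embed one tile: summary features expanded by a fixed random projection.

    The projection matrix depends only on (d, seed), so identical tiles give
    identical embeddings and the map is Lipschitz in pixel values.
    """
    feats = mock_tile_features(tile)
    rng = np.random.default_rng(np.random.SeedSequence([seed, d, 0x3A7]))
    proj = rng.standard_normal((d, feats.size)) / np.sqrt(feats.size)
    return proj @ feats


def mock_encoder(d: int = 64, seed: int = 0, name: str = "mock") -> EncoderSpec:
    """EncoderSpec wrapping :func:`mock_encode` with a cached projection."""
    n_feats = 3 * (2 + 2 * _N_HARMONICS)
    rng = np.random.default_rng(np.random.SeedSequence([seed, d, 0x3A7]))
    proj = rng.standard_normal((d, n_feats)) / np.sqrt(n_feats)

    def fn(tile: np.ndarray) -> np.ndarray:
        return proj @ mock_tile_features(tile)

    return EncoderSpec(name=name, embed_dim=d, fn=fn)


def _apply_transform(tile: np.ndarray, spec: EncoderSpec) -> np.ndarray:
    if spec.crop is not None:
        h, w = tile.shape[:2]
        if spec.crop > min(h, w):
            raise ValueError(f"crop {spec.crop} exceeds tile size {(h, w)}")
        y0 = (h - spec.crop) // 2
        x0 = (w - spec.crop) // 2
        tile = tile[y0 : y0 + spec.crop, x0 : x0 + spec.crop]
    return tile


def encode_slide(
    encoder: EncoderSpec,
    tiles: Sequence[np.ndarray],
    coords: Sequence[tuple[int, int]],
    slide_id: str = "slide",
) -> TileEmbeddingMatrix:
    """Encode a slide's kept tiles into a TileEmbeddingMatrix.

    Row order follows the input coordinate order.  Raises on an empty tile
    set ("slide has no foreground tiles").
    """
    tiles = list(tiles)
    coords = list(coords)
    if len(tiles) == 0:
        raise EmbeddingIOError(f"slide {slide_id!r} has no foreground tiles")
    if len(tiles) != len(coords):
        raise ValueError("tiles and coords must have equal length")
    shapes = {t.shape for t in map(np.asarray, tiles)}
    if len(shapes) != 1:
        raise ValueError(f"tiles have inconsistent shapes: {sorted(shapes)}")
    rows = np.stack([encoder.fn(_apply_transform(np.asarray(t), encoder)) for t in tiles])
    return TileEmbeddingMatrix(
        slide_id=slide_id,
        encoder_name=encoder.name,
        matrix=rows.astype(np.float32),
        coords=np.asarray(coords, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# Persistence: binary container + coords sidecar CSV
# ---------------------------------------------------------------------------
#
# Layout: 4-byte magic "WSEM", uint32 little-endian header length, JSON
# header {version, n_tiles, dim, slide_id, encoder_name}, then row-major
# float32 payload of n_tiles * dim values.  Coordinates live in a sidecar
# CSV "<path>.coords.csv" with columns row,col.


def coords_sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".coords.csv")


def store_embeddings(m: TileEmbeddingMatrix, path: str | Path) -> None:
    m.validate()
    path = Path(path)
    header = json.dumps(
        {
            "version": _VERSION,
            "n_tiles": int(m.n_tiles),
            "dim": int(m.dim),
            "slide_id": m.slide_id,
            "encoder_name": m.encoder_name,
        }
    ).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(np.uint32(len(header)).tobytes())
        fh.write(header)
        fh.write(np.ascontiguousarray(m.matrix, dtype="<f4").tobytes())
    pd.DataFrame(m.coords, columns=["row", "col"]).to_csv(
        coords_sidecar_path(path), index=False
    )


def load_embeddings(path: str | Path) -> TileEmbeddingMatrix:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic != _MAGIC:
            raise EmbeddingIOError(f"{path}: bad magic {magic!r}")
        (hlen,) = np.frombuffer(fh.read(4), dtype="<u4")
        header = json.loads(fh.read(int(hlen)).decode())
        if header["version"] != _VERSION:
            raise EmbeddingIOError(f"{path}: unsupported version {header['version']}")
        n, d = int(header["n_tiles"]), int(header["dim"])
        payload = fh.read()
    mat = np.frombuffer(payload, dtype="<f4")
    if mat.size != n * d:
        raise EmbeddingIOError(
            f"{path}: payload has {mat.size} values, expected {n * d}"
        )
    sidecar = coords_sidecar_path(path)
    if not sidecar.exists():
        raise EmbeddingIOError(f"missing coords sidecar {sidecar}")
    coords = pd.read_csv(sidecar)[["row", "col"]].to_numpy()
    if coords.shape[0] != n:
        raise EmbeddingIOError(
            f"{sidecar}: {coords.shape[0]} coordinate rows for {n} embeddings"
        )
    return TileEmbeddingMatrix(
        slide_id=header["slide_id"],
        encoder_name=header["encoder_name"],
        matrix=mat.reshape(n, d).copy(),
        coords=coords,
    )
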