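"""Collapse a variable-length bag of tile embeddings into one slide embedding.

Two aggregators are provided:

* **GAP** — global average pooling, the unweighted coordinatewise mean of
  tile embeddings; assumes all tiles are equally informative.
* **ABMIL** — attention-based multiple-instance learning: a small score
  network assigns each tile a weight, weights are softmax-normalized within
  each attention branch, and the slide embedding is the attention-weighted
  mean, concatenated across branches and linearly projected back to the
  input dimension d.  Score networks follow the standard formulation —
  ungated ``e_k = w^T tanh(V h_k)``, gated ``e_k = w^T (tanh(V h_k) *
  sigmoid(U h_k))`` — with 1 or 8 parallel branches.

Tile positions are optionally injected by *adding* 2D sinusoidal positional
embeddings (half the dimensions encode the row, half the column, at
geometric frequencies with base 10,000) to tile embeddings before scoring.

The forward pass is written with an explicit cache so the joint trainer in
:mod:`wsimil.classify` can backpropagate through it; gradients are exact
and verified against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .embedding import TileEmbeddingMatrix
from .tiling import TileGrid


@dataclass
class SlideEmbedding:
    slide_id: str
    vector: np.ndarray
    aggregator_name: str

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector)
        if self.vector.ndim != 1 or not np.all(np.isfinite(self.vector)):
            raise ValueError("slide embedding must be a finite 1-D vector")


@dataclass
class AttentionRecord:
    """Per-branch softmax attention weights over a slide's tiles."""

    slide_id: str
    weights: np.ndarray  # (n_branches, n_tiles), rows sum to 1
    coords: np.ndarray  # (n_tiles, 2)

    def __post_init__(self) -> None:
        self.weights = np.atleast_2d(np.asarray(self.weights))
        sums = self.weights.sum(axis=1)
        if np.any(self.weights < -1e-9) or np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("attention weights must be non-negative and sum to 1")

    def branch_mean(self) -> np.ndarray:
        return self.weights.mean(axis=0)


def gap_aggregate(m: TileEmbeddingMatrix) -> SlideEmbedding:
    """Coordinatewise arithmetic mean of tile embeddings."""
    if m.n_tiles < 1:
        raise ValueError("cannot aggregate an empty bag")
    return SlideEmbedding(
        slide_id=m.slide_id,
        vector=m.matrix.astype(np.float64).mean(axis=0),
        aggregator_name="gap",
    )


# ---------------------------------------------------------------------------
# 2D sinusoidal positional embedding
# ---------------------------------------------------------------------------

_POS_BASE = 10_000.0


def _axis_encoding(pos: np.ndarray, m: int) -> np.ndarray:
    """1-D sinusoidal encoding of positions into m dims (alternating sin/cos)."""
    j = np.arange(m // 2, dtype=np.float64)
    omega = _POS_BASE ** (-2.0 * j / m)
    ang = np.asarray(pos, dtype=np.float64)[..., None] * omega  # (..., m/2)
    out = np.empty(ang.shape[:-1] + (m,), dtype=np.float64)
    out[..., 0::2] = np.sin(ang)
    out[..., 1::2] = np.cos(ang)
    return out


def positional_embedding_2d(row: int, col: int, d: int) -> np.ndarray:
    """d-vector encoding (row, col); first d/2 dims encode row, last d/2 col."""
    if d % 4 != 0:
        raise ValueError("positional embedding dimension must be divisible by 4")
    if row < 0 or col < 0:
        raise ValueError("row and col must be non-negative")
    half = d // 2
    return np.concatenate([_axis_encoding(row, half), _axis_encoding(col, half)])


def positional_embedding_grid(coords: np.ndarray, d: int) -> np.ndarray:
    """(n, d) positional embeddings for an array of (row, col) coords."""
    if d % 4 != 0:
        raise ValueError("positional embedding dimension must be divisible by 4")
    coords = np.asarray(coords)
    half = d // 2
    return np.concatenate(
        [_axis_encoding(coords[:, 0], half), _axis_encoding(coords[:, 1], half)], axis=1
    )


# ---------------------------------------------------------------------------
# ABMIL
# ---------------------------------------------------------------------------


@dataclass
class AbmilParams:
    """Weights of the attention score networks and the output projection.

    Shapes: ``V``/``U`` are (n_branches, hidden, d), ``w`` (n_branches,
    hidden), ``proj`` (d, n_branches * d), ``bias`` (d).  ``U`` is None for
    the ungated variant.
    """

    V: np.ndarray
    U: np.ndarray | None
    w: np.ndarray
    proj: np.ndarray
    bias: np.ndarray
    gated: bool
    seed: int = 0

    @property
    def n_branches(self) -> int:
        return self.V.shape[0]

    @property
    def hidden_dim(self) -> int:
        return self.V.shape[1]

    @property
    def dim(self) -> int:
        return self.V.shape[2]

    @classmethod
    def init(
        cls,
        d: int,
        hidden_dim: int = 128,
        n_branches: int = 1,
        gated: bool = False,
        seed: int = 0,
        dtype=np.float64,
    ) -> "AbmilParams":
        """Fan-in-scaled uniform initialization, seeded."""
        if n_branches < 1 or hidden_dim < 1:
            raise ValueError("n_branches and hidden_dim must be >= 1")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xAB11]))

        def uni(shape, fan_in):
            lim = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-lim, lim, size=shape).astype(dtype)

        return cls(
            V=uni((n_branches, hidden_dim, d), d),
            U=uni((n_branches, hidden_dim, d), d) if gated else None,
            w=uni((n_branches, hidden_dim), hidden_dim),
            proj=uni((d, n_branches * d), n_branches * d),
            bias=np.zeros(d, dtype=dtype),
            gated=gated,
            seed=seed,
        )

    def as_dict(self) -> dict[str, np.ndarray]:
        out = {"V": self.V, "w": self.w, "proj": self.proj, "bias": self.bias}
        if self.gated:
            out["U"] = self.U
        return out


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max()
    e = np.exp(z)
    return e / e.sum()


def abmil_forward(
    H: np.ndarray, params: AbmilParams, return_cache: bool = False
):
    """Forward pass over a bag H (n_tiles, d); returns (s, A[, cache]).

    ``s`` is the projected slide embedding (d,), ``A`` the (n_branches,
    n_tiles) attention weights.  Raises on an empty bag or non-finite
    attention.
    """
    H = np.asarray(H)
    if H.ndim != 2 or H.shape[0] < 1:
        raise ValueError("bag must be a non-empty (n_tiles, d) matrix")
    if H.shape[1] != params.dim:
        raise ValueError(f"bag dim {H.shape[1]} != params dim {params.dim}")
    B = params.n_branches
    # branch loop keeps every product a plain BLAS matmul
    T = np.stack([np.tanh(H @ params.V[b].T) for b in range(B)])  # (B, n, hidden)
    if params.gated:
        G = np.stack(
            [1.0 / (1.0 + np.exp(-(H @ params.U[b].T))) for b in range(B)]
        )
        M = T * G
    else:
        G = None
        M = T
    E = np.stack([M[b] @ params.w[b] for b in range(B)])  # scores (B, n)
    A = np.stack([_softmax(E[b]) for b in range(B)])  # (B, n)
    if not np.all(np.isfinite(A)):
        raise FloatingPointError("non-finite attention weights")
    Z = A @ H  # (B, d) branch outputs
    z = Z.reshape(-1)  # concatenated (B*d,)
    s = params.proj @ z + params.bias
    if not return_cache:
        return s, A
    cache = {"H": H, "T": T, "G": G, "M": M, "A": A, "z": z}
    return s, A, cache


def abmil_backward(
    ds: np.ndarray, params: AbmilParams, cache: dict
) -> dict[str, np.ndarray]:
    """Exact gradients of a scalar loss wrt ABMIL parameters.

    ``ds`` is dL/ds for the projected slide embedding.  Tile embeddings are
    frozen inputs, so dL/dH is not computed.
    """
    H, T, G, M, A = cache["H"], cache["T"], cache["G"], cache["M"], cache["A"]
    B, d = params.n_branches, params.dim
    grads: dict[str, np.ndarray] = {}
    grads["bias"] = ds.copy()
    grads["proj"] = np.outer(ds, cache["z"])
    dz = (params.proj.T @ ds).reshape(B, d)  # per-branch dL/dZ_b
    dA = dz @ H.T  # (B, n)
    dE = A * (dA - (A * dA).sum(axis=1, keepdims=True))  # softmax backward
    grads["w"] = np.stack([M[b].T @ dE[b] for b in range(B)])
    dM = dE[:, :, None] * params.w[:, None, :]  # (B, n, hidden)
    if params.gated:
        dT = (1.0 - T**2) * dM * G
        dGz = G * (1.0 - G) * dM * T
        grads["V"] = np.stack([dT[b].T @ H for b in range(B)])
        grads["U"] = np.stack([dGz[b].T @ H for b in range(B)])
    else:
        dT = (1.0 - T**2) * dM
        grads["V"] = np.stack([dT[b].T @ H for b in range(B)])
    return grads


def abmil_aggregate(
    m: TileEmbeddingMatrix,
    params: AbmilParams,
    use_positional: bool = True,
) -> tuple[SlideEmbedding, AttentionRecord]:
    """Aggregate one bag with ABMIL; returns the embedding and attention.

    With ``use_positional`` the 2D sinusoidal positional embedding of each
    tile's (row, col) is added to its embedding before scoring.
    """
    H = m.matrix.astype(np.float64)
    if use_positional:
        H = H + positional_embedding_grid(m.coords, m.dim)
    s, A = abmil_forward(H, params)
    emb = SlideEmbedding(slide_id=m.slide_id, vector=s, aggregator_name="abmil")
    att = AttentionRecord(slide_id=m.slide_id, weights=A, coords=m.coords.copy())
    return emb, att


# ---------------------------------------------------------------------------
# Attention heatmap rendering
# ---------------------------------------------------------------------------


def render_attention_heatmap(
    att: AttentionRecord,
    grid: TileGrid,
    base_image: np.ndarray | None = None,
    cmap: str = "viridis",
    alpha: float = 0.5,
    out_path: str | Path | None = None,
) -> np.ndarray:
    """Rasterize attention as a per-tile colour overlay (uint8 RGB).

    Branch weights are averaged, min-max normalized within the slide (a
    constant field maps to 0.5), coloured through a matplotlib colormap,
    and alpha-blended over ``base_image`` when given.
    """
    import matplotlib as mpl
    from PIL import Image

    kept = {tuple(rc) for rc in grid.kept()[["row", "col"]].to_numpy().tolist()}
    for rc in att.coords.tolist():
        if tuple(rc) not in kept:
            raise ValueError(f"attention coord {tuple(rc)} not among kept grid tiles")

    w = att.branch_mean()
    lo, hi = float(w.min()), float(w.max())
    norm = np.full_like(w, 0.5) if hi - lo < 1e-15 else (w - lo) / (hi - lo)
    colors = (mpl.colormaps[cmap](norm)[:, :3] * 255).astype(np.uint8)

    ts = grid.tile_size
    h, wd = grid.n_rows * ts, grid.n_cols * ts
    overlay = np.zeros((h, wd, 3), dtype=np.uint8)
    painted = np.zeros((h, wd), dtype=bool)
    for (r, c), rgb in zip(att.coords.tolist(), colors):
        overlay[r * ts : (r + 1) * ts, c * ts : (c + 1) * ts] = rgb
        painted[r * ts : (r + 1) * ts, c * ts : (c + 1) * ts] = True

    if base_image is not None:
        base = np.asarray(base_image)[:h, :wd].astype(np.float64)
        out = base.copy()
        out[painted] = (1 - alpha) * base[painted] + alpha * overlay[painted]
        overlay = np.clip(out, 0, 255).astype(np.uint8)

    if out_path is not None:
        Image.fromarray(overlay).save(out_path)
    return overlay


def attention_to_frame(att: AttentionRecord, slide_id: str | None = None):
    """Long-form DataFrame slide_id,branch,row,col,weight for CSV export."""
    import pandas as pd

    B, n = att.weights.shape
    return pd.DataFrame(
        {
            "slide_id": (slide_id or att.slide_id),
            "branch": np.repeat(np.arange(B), n),
            "row": np.tile(att.coords[:, 0], B),
            "col": np.tile(att.coords[:, 1], B),
            "weight": att.weights.ravel(),
        }
    )
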