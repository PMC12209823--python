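"""Few-shot tile annotation from per-class prototype embeddings.

A handful of slides are annotated with quadrangular bounding boxes around
tissues of interest (seven classes by default: invasive SCC, Bowen,
superficial BCC, nodular BCC, epidermis, dermis/subcutis, artifact).  Tiles
whose footprint centers fall inside a box are pooled per class, and global
average pooling over each class's tile embeddings yields one
*representative* (prototype) embedding per class.  Inference requires no
training at all: every tile of a new slide is scored against each
prototype by the raw dot product and labelled with the argmax class.

The dot product is deliberately unnormalized — prototype magnitude carries
information — so doubling a prototype's norm genuinely changes the
predictions; cosine similarity is available behind a flag but never the
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .embedding import TileEmbeddingMatrix
from .tiling import TileGrid

DEFAULT_TISSUE_CLASSES: tuple[str, ...] = (
    "invasive_scc",
    "bowen",
    "superficial_bcc",
    "nodular_bcc",
    "epidermis",
    "dermis_subcutis",
    "artifact",
)

ROI_COLUMNS = ["slide_id", "class", "x0", "y0", "x1", "y1"]


@dataclass(frozen=True)
class RoiAnnotation:
    """Half-open pixel bounding box labelled with a tissue class."""

    slide_id: str
    label: str
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(f"degenerate ROI box {(self.x0, self.y0, self.x1, self.y1)}")

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1


@dataclass
class RepresentativeEmbeddingSet:
    """One prototype embedding per tissue class, with provenance."""

    classes: tuple[str, ...]
    matrix: np.ndarray  # (n_classes, d)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape[0] != len(self.classes):
            raise ValueError("one embedding per class required")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("prototype embeddings must be finite")

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def to_json(self, path: str | Path) -> None:
        import json

        payload = {
            "classes": list(self.classes),
            "embeddings": self.matrix.tolist(),
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "RepresentativeEmbeddingSet":
        import json

        payload = json.loads(Path(path).read_text())
        return cls(
            classes=tuple(payload["classes"]),
            matrix=np.asarray(payload["embeddings"]),
            provenance=payload.get("provenance", {}),
        )


def read_rois(path: str | Path) -> list[RoiAnnotation]:
    df = pd.read_csv(path)
    return [
        RoiAnnotation(
            slide_id=str(r["slide_id"]),
            label=str(r["class"]),
            x0=int(r["x0"]),
            y0=int(r["y0"]),
            x1=int(r["x1"]),
            y1=int(r["y1"]),
        )
        for _, r in df.iterrows()
    ]


def write_rois(rois: list[RoiAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [(r.slide_id, r.label, r.x0, r.y0, r.x1, r.y1) for r in rois],
        columns=ROI_COLUMNS,
    ).to_csv(path, index=False)


def extract_roi_tiles(
    grid: TileGrid, rois: list[RoiAnnotation]
) -> dict[str, np.ndarray]:
    """Kept-tile indices per class, by the center-in-box rule.

    Indices refer to positions in the kept-tile sequence (row-major scan
    order), matching embedding-matrix rows.  A tile inside several
    same-class boxes counts once; a tile claimed by two different classes
    is an annotation conflict and raises, listing the offenders.
    """
    import logging

    kept = grid.kept().reset_index(drop=True)
    ts = grid.tile_size
    cx = kept["x0"].to_numpy() + ts / 2.0
    cy = kept["y0"].to_numpy() + ts / 2.0
    per_class: dict[str, set[int]] = {}
    owner: dict[int, str] = {}
    conflicts = []
    for roi in rois:
        inside = np.flatnonzero(
            (cx >= roi.x0) & (cx < roi.x1) & (cy >= roi.y0) & (cy < roi.y1)
        )
        if len(inside) == 0:
            logging.getLogger(__name__).warning(
                "ROI %s/%s covers no tile centers", roi.slide_id, roi.label
            )
        for idx in inside:
            prev = owner.get(int(idx))
            if prev is not None and prev != roi.label:
                conflicts.append((int(idx), prev, roi.label))
            owner[int(idx)] = roi.label if prev is None else prev
            per_class.setdefault(roi.label, set()).add(int(idx))
    if conflicts:
        raise ValueError(
            "tiles claimed by multiple classes: "
            + ", ".join(f"tile {i} ({a} vs {b})" for i, a, b in conflicts[:10])
        )
    return {cls: np.array(sorted(idx)) for cls, idx in per_class.items()}


def build_prototypes(
    per_class_embeddings: dict[str, np.ndarray],
    classes: tuple[str, ...] = DEFAULT_TISSUE_CLASSES,
    provenance: dict | None = None,
) -> RepresentativeEmbeddingSet:
    """Global average pooling of each class's ROI tile embeddings.

    Tiles are pooled directly across all source slides and ROIs of a class.
    Raises if any configured class has no tiles, naming the class.
    """
    rows = []
    counts = {}
    for cls in classes:
        emb = per_class_embeddings.get(cls)
        if emb is None or len(emb) == 0:
            raise ValueError(f"class {cls!r} has no ROI tiles")
        emb = np.atleast_2d(np.asarray(emb, dtype=np.float64))
        rows.append(emb.mean(axis=0))
        counts[cls] = int(emb.shape[0])
    prov = dict(provenance or {})
    prov["tile_counts"] = counts
    return RepresentativeEmbeddingSet(classes=tuple(classes), matrix=np.stack(rows), provenance=prov)


def prototypes_from_slides(
    slides: list, classes: tuple[str, ...] = DEFAULT_TISSUE_CLASSES
) -> RepresentativeEmbeddingSet:
    """Pool ROI tiles across annotated slides and build prototypes.

    ``slides`` holds objects with ``embeddings`` (TileEmbeddingMatrix),
    ``rois``, ``grid_shape`` and ``tile_size`` — e.g. the synthetic
    annotated-slide fixtures.
    """
    from .tiling import tile_grid

    pooled: dict[str, list[np.ndarray]] = {c: [] for c in classes}
    sources = []
    for s in slides:
        n_rows, n_cols = s.grid_shape
        grid = tile_grid(
            n_cols * s.tile_size, n_rows * s.tile_size, s.tile_size,
            slide_id=s.embeddings.slide_id,
        )
        idx = extract_roi_tiles(grid, s.rois)
        for cls, tiles in idx.items():
            if cls in pooled and len(tiles):
                pooled[cls].append(s.embeddings.matrix[tiles])
        sources.append(s.embeddings.slide_id)
    per_class = {
        cls: np.concatenate(chunks) for cls, chunks in pooled.items() if chunks
    }
    return build_prototypes(per_class, classes, provenance={"source_slides": sources})


def annotate_tiles(
    m: TileEmbeddingMatrix,
    protos: RepresentativeEmbeddingSet,
    cosine: bool = False,
) -> pd.DataFrame:
    """Label every tile with its most similar prototype (raw dot product).

    Pure function of the inputs — no training, no parameter updates.
    Returns a frame with row, col, predicted_class, score_<class>...,
    ambiguous; exact score ties resolve to the first class in configured
    order and flag the tile ambiguous.
    """
    if m.dim != protos.dim:
        raise ValueError(f"embedding dim {m.dim} != prototype dim {protos.dim}")
    P = protos.matrix
    if cosine:
        P = P / np.linalg.norm(P, axis=1, keepdims=True)
        X = m.matrix.astype(np.float64)
        X = X / np.linalg.norm(X, axis=1, keepdims=True)
        scores = X @ P.T
    else:
        scores = m.matrix.astype(np.float64) @ P.T
    pred_idx = np.argmax(scores, axis=1)
    top = scores[np.arange(len(scores)), pred_idx]
    ambiguous = (np.abs(scores - top[:, None]) < 1e-12).sum(axis=1) > 1
    out = pd.DataFrame(
        {
            "row": m.coords[:, 0],
            "col": m.coords[:, 1],
            "predicted_class": [protos.classes[i] for i in pred_idx],
        }
    )
    for j, cls in enumerate(protos.classes):
        out[f"score_{cls}"] = scores[:, j]
    out["ambiguous"] = ambiguous
    return out


def pca_2d(protos: RepresentativeEmbeddingSet) -> pd.DataFrame:
    """First two principal components of the mean-centered prototypes.

    Component signs are fixed by making each component's largest-magnitude
    loading positive, so results are fully deterministic.  Requires at
    least 3 classes; collinear (rank-1) prototypes give second components
    of exactly zero, while fully coincident prototypes are an error.
    """
    if len(protos.classes) < 3:
        raise ValueError("PCA of prototypes requires at least 3 classes")
    X = protos.matrix - protos.matrix.mean(axis=0)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    if s[0] <= 1e-12:
        raise ValueError("prototypes are coincident; no principal directions")
    if s[1] <= 1e-10 * s[0]:
        s = s.copy()
        s[1] = 0.0  # collinear prototypes: flatten the second component
    comps = vt[:2]
    for i in range(2):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    coords = X @ comps.T
    if s[1] == 0.0:
        coords[:, 1] = 0.0
    return pd.DataFrame(
        {"class": protos.classes, "pc1": coords[:, 0], "pc2": coords[:, 1]}
    )


_PALETTE = (  # deterministic palette keyed by class order
    (31, 119, 180),
    (255, 127, 14),
    (44, 160, 44),
    (214, 39, 40),
    (148, 103, 189),
    (140, 86, 75),
    (227, 119, 194),
    (127, 127, 127),
    (188, 189, 34),
    (23, 190, 207),
)


def class_palette(classes: tuple[str, ...]) -> dict[str, tuple[int, int, int]]:
    return {cls: _PALETTE[i % len(_PALETTE)] for i, cls in enumerate(classes)}


def render_annotation_overlay(
    annotation: pd.DataFrame,
    grid: TileGrid,
    classes: tuple[str, ...],
    base_image: np.ndarray | None = None,
    alpha: float = 0.5,
    out_path: str | Path | None = None,
) -> np.ndarray:
    """Per-tile class-coloured overlay (uint8 RGB) plus optional PNG/legend.

    When ``out_path`` is given the raster is saved there and a legend
    sidecar CSV (class, r, g, b) next to it.
    """
    from PIL import Image

    palette = class_palette(classes)
    ts = grid.tile_size
    h, w = grid.n_rows * ts, grid.n_cols * ts
    overlay = np.zeros((h, w, 3), dtype=np.uint8)
    painted = np.zeros((h, w), dtype=bool)
    for _, t in annotation.iterrows():
        r, c = int(t["row"]), int(t["col"])
        overlay[r * ts : (r + 1) * ts, c * ts : (c + 1) * ts] = palette[
            t["predicted_class"]
        ]
        painted[r * ts : (r + 1) * ts, c * ts : (c + 1) * ts] = True
    if base_image is not None:
        base = np.asarray(base_image)[:h, :w].astype(np.float64)
        out = base.copy()
        out[painted] = (1 - alpha) * base[painted] + alpha * overlay[painted]
        overlay = np.clip(out, 0, 255).astype(np.uint8)
    if out_path is not None:
        out_path = Path(out_path)
        Image.fromarray(overlay).save(out_path)
        legend = pd.DataFrame(
            [(cls, *palette[cls]) for cls in classes],
            columns=["class", "r", "g", "b"],
        )
        legend.to_csv(out_path.with_suffix(".legend.csv"), index=False)
    return overlay
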