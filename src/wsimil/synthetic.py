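"""Synthetic cohorts, tissue-like images, and tile-embedding bags.

The real study cohort (H&E whole-slide images of nonmelanoma skin cancer
biopsies from 455 patients) is private, and its foundation-model encoders
are GPU-scale.  This module generates data with the same *statistical
structure* the pipeline assumes, so every downstream stage is testable:

* a patient -> biopsy -> slide hierarchy over the four diagnostic classes
  (Benign, Bowen, BCC, SCC), with an exact published-count mode;
* bright-background images with darker elliptical tissue blobs plus the
  ground-truth foreground mask, as fixtures for tiling;
* per-slide embedding bags realising the multiple-instance premise: only a
  small fraction of tiles on a cancerous slide carries the label signal.

Embedding model: background tiles ~ N(0, sigma^2 I).  Each class has a
prototype mean at distance ``class_separation`` (Delta) from the origin
along mutually orthogonal seeded directions.  A non-benign slide with n
tiles has max(1, round(diag_fraction * n)) diagnostic tiles drawn at the
class prototype, the rest at background; a benign slide draws *all* tiles
at a milder benign shift (default Delta / 2), making Benign a learnable
class rather than pure noise.  Setting Delta = 0 removes all signal.

Background tiles are not a single blob of noise: each slide mixes K shared
background *tissue-type* prototypes (think epidermis, dermis, subcutis,
artifact...) in slide-specific proportions drawn from a Dirichlet.  This
matters for the multiple-instance premise: with a purely i.i.d. background
the slide mean would be a sufficient statistic (tile noise averages out as
sigma/sqrt(n)) and mean pooling could never be beaten by attention at any
dilution.  Slide-varying tissue composition confounds the mean — the
mixture prototypes overlap the class directions — while individual
diagnostic tiles remain cleanly separable, which is precisely the regime
where instance attention earns its keep.  Because the prototypes are
shared across slides, there is no per-slide fingerprint to memorize;
setting ``n_background_types = 0`` recovers the plain isotropic background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .embedding import TileEmbeddingMatrix
from .errors import ConfigurationError, ManifestError

logger = logging.getLogger(__name__)

CLASSES: tuple[str, ...] = ("Benign", "Bowen", "BCC", "SCC")
#: ascending clinical severity; used to break most-frequent-label ties
SEVERITY: tuple[str, ...] = ("Benign", "Bowen", "BCC", "SCC")

#: published cohort counts per class (patients, biopsies) and total slides
TABLE2_PATIENTS: tuple[int, ...] = (210, 140, 85, 20)
TABLE2_BIOPSIES: tuple[int, ...] = (229, 171, 116, 37)
TABLE2_SLIDES_TOTAL: int = 2130

# sub-seed stream tags (arbitrary distinct constants)
_S_COHORT, _S_DIRS, _S_TILES, _S_EMB, _S_IMG, _S_FEWSHOT = 11, 23, 37, 53, 71, 89


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration; defaults define the desk-scale study conditions."""

    seed: int = 0
    n_patients_per_class: tuple[int, int, int, int] = (10, 10, 10, 10)
    biopsies_per_patient_dist: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.80, 2: 0.19, 3: 0.01}
    )
    slides_per_biopsy_dist: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.10, 3: 0.24, 4: 0.44, 5: 0.15, 6: 0.07}
    )
    tiles_per_slide_range: tuple[int, int] = (50, 2000)
    embed_dim: int = 64
    diag_fraction: float = 0.3
    class_separation: float = 4.0  # Delta
    noise_sd: float = 1.0  # sigma
    benign_separation: float | None = None  # Delta_benign, defaults to Delta / 2
    n_background_types: int = 64  # K shared background micro-environment states
    background_scale: float = 3.0  # prototype distance from the origin
    background_dirichlet_alpha: float = 0.2  # slide-level mixture concentration
    table2_mode: bool = False

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_patients_per_class):
            raise ConfigurationError("patient counts must be non-negative")
        lo, hi = self.tiles_per_slide_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("tiles_per_slide_range must satisfy 1 <= min <= max")
        if self.embed_dim < 4:
            raise ConfigurationError("embed_dim must be >= 4 (orthogonal class prototypes)")
        if not (0.0 < self.diag_fraction <= 1.0):
            raise ConfigurationError("diag_fraction must be in (0, 1]")
        if self.class_separation < 0:
            raise ConfigurationError("class_separation must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.n_background_types < 0:
            raise ConfigurationError("n_background_types must be >= 0")
        if self.background_scale < 0 or self.background_dirichlet_alpha <= 0:
            raise ConfigurationError("background mixture parameters must be positive")
        for name, dist in (
            ("biopsies_per_patient_dist", self.biopsies_per_patient_dist),
            ("slides_per_biopsy_dist", self.slides_per_biopsy_dist),
        ):
            if not dist or any(p < 0 for p in dist.values()):
                raise ConfigurationError(f"{name} must be a non-empty distribution")
            if abs(sum(dist.values()) - 1.0) > 1e-6:
                raise ConfigurationError(f"{name} probabilities must sum to 1")
            if any(k < 1 for k in dist):
                raise ConfigurationError(f"{name} support must be positive integers")

    @property
    def delta_benign(self) -> float:
        if self.benign_separation is not None:
            if self.benign_separation > self.class_separation:
                raise ConfigurationError("benign_separation must be <= class_separation")
            return self.benign_separation
        return self.class_separation / 2.0


@dataclass
class CohortManifest:
    """Patient -> biopsy -> slide hierarchy with subtype labels."""

    patients: pd.DataFrame  # patient_id, patient_label
    biopsies: pd.DataFrame  # biopsy_id, patient_id, biopsy_label
    slides: pd.DataFrame  # slide_id, biopsy_id, path

    def validate(self) -> None:
        for col, df, name in (
            ("patient_id", self.patients, "patients"),
            ("biopsy_id", self.biopsies, "biopsies"),
            ("slide_id", self.slides, "slides"),
        ):
            if df[col].duplicated().any():
                dup = df.loc[df[col].duplicated(), col].iloc[0]
                raise ManifestError(f"duplicate {col} {dup!r} in {name}")
        bad = set(self.biopsies["biopsy_label"]) - set(CLASSES)
        if bad:
            raise ManifestError(f"unknown biopsy labels {sorted(bad)}")
        pat_ids = set(self.patients["patient_id"])
        for _, row in self.biopsies.iterrows():
            if row["patient_id"] not in pat_ids:
                raise ManifestError(
                    f"biopsy {row['biopsy_id']!r} references missing patient "
                    f"{row['patient_id']!r}"
                )
        bio_ids = set(self.biopsies["biopsy_id"])
        for _, row in self.slides.iterrows():
            if row["biopsy_id"] not in bio_ids:
                raise ManifestError(
                    f"slide {row['slide_id']!r} references missing biopsy "
                    f"{row['biopsy_id']!r}"
                )
        # patient label = most frequent biopsy label, severity breaking ties
        derived = derive_patient_labels(self.biopsies)
        for _, row in self.patients.iterrows():
            want = derived.get(row["patient_id"])
            if want is not None and row["patient_label"] != want:
                raise ManifestError(
                    f"patient {row['patient_id']!r} labelled {row['patient_label']!r}, "
                    f"expected most-frequent biopsy label {want!r}"
                )
        if len(self.slides) == 0:
            logger.warning("manifest has zero slides")

    def equals(self, other: "CohortManifest") -> bool:
        return (
            self.patients.reset_index(drop=True).equals(other.patients.reset_index(drop=True))
            and self.biopsies.reset_index(drop=True).equals(other.biopsies.reset_index(drop=True))
            and self.slides.reset_index(drop=True).equals(other.slides.reset_index(drop=True))
        )

    def slide_labels(self) -> pd.Series:
        """Label per slide (inherited from its biopsy), indexed by slide_id."""
        merged = self.slides.merge(self.biopsies, on="biopsy_id", how="left")
        return merged.set_index("slide_id")["biopsy_label"]


@dataclass
class DiagnosticMask:
    """Ground-truth flags marking the label-bearing tiles of one slide."""

    slide_id: str
    flags: np.ndarray  # bool per tile

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)


def derive_patient_labels(biopsies: pd.DataFrame) -> dict[str, str]:
    """Most frequent biopsy label per patient; ties broken by severity (SCC first)."""
    out: dict[str, str] = {}
    for pid, grp in biopsies.groupby("patient_id"):
        counts = grp["biopsy_label"].value_counts()
        top = counts.max()
        tied = [c for c in counts.index if counts[c] == top]
        out[pid] = max(tied, key=SEVERITY.index)
    return out


def _rng(cfg_seed: int, stream: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg_seed, stream, *key]))


def _draw_counts(dist: Mapping[int, float], n: int, rng: np.random.Generator) -> np.ndarray:
    vals = np.array(sorted(dist))
    probs = np.array([dist[v] for v in vals])
    return rng.choice(vals, size=n, p=probs)


def _adjust_total(counts: np.ndarray, target: int, lo: int, hi: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Nudge drawn integer counts (each within [lo, hi]) to an exact total."""
    counts = counts.copy()
    if not (lo * len(counts) <= target <= hi * len(counts)):
        raise ConfigurationError(
            f"cannot reach total {target} with {len(counts)} draws in [{lo}, {hi}]"
        )
    delta = target - int(counts.sum())
    while delta != 0:
        step = 1 if delta > 0 else -1
        candidates = np.flatnonzero((counts < hi) if step > 0 else (counts > lo))
        idx = rng.choice(candidates)
        counts[idx] += step
        delta -= step
    return counts


def generate_cohort(cfg: SyntheticConfig) -> CohortManifest:
    """Generate a cohort manifest; deterministic given ``cfg.seed``.

    In ``table2_mode`` the per-class patient and biopsy counts and the total
    slide count reproduce the published cohort exactly; otherwise patients
    per class come from ``n_patients_per_class`` with biopsy and slide
    counts drawn from the configured distributions.
    """
    rng = _rng(cfg.seed, _S_COHORT)
    patients: list[tuple[str, str]] = []
    biopsies: list[tuple[str, str, str]] = []

    if cfg.table2_mode:
        n_pat, n_bio = TABLE2_PATIENTS, TABLE2_BIOPSIES
    else:
        n_pat, n_bio = cfg.n_patients_per_class, None

    pat_idx = bio_idx = 0
    for ci, cls in enumerate(CLASSES):
        cls_patients = []
        for _ in range(n_pat[ci]):
            pid = f"P{pat_idx:04d}"
            pat_idx += 1
            cls_patients.append(pid)
            patients.append((pid, cls))
        if not cls_patients:
            continue
        if cfg.table2_mode:
            # one biopsy per patient, extras spread over seeded random patients
            extra = n_bio[ci] - n_pat[ci]
            if extra < 0:
                raise ConfigurationError(f"fewer biopsies than patients for {cls}")
            per_patient = np.ones(len(cls_patients), dtype=int)
            for idx in rng.choice(len(cls_patients), size=extra, replace=True):
                per_patient[idx] += 1
        else:
            per_patient = _draw_counts(cfg.biopsies_per_patient_dist, len(cls_patients), rng)
        for pid, k in zip(cls_patients, per_patient):
            for _ in range(k):
                biopsies.append((f"B{bio_idx:04d}", pid, cls))
                bio_idx += 1

    bio_df = pd.DataFrame(biopsies, columns=["biopsy_id", "patient_id", "biopsy_label"])
    slide_vals = sorted(cfg.slides_per_biopsy_dist)
    per_biopsy = _draw_counts(cfg.slides_per_biopsy_dist, len(bio_df), rng)
    if cfg.table2_mode:
        per_biopsy = _adjust_total(
            per_biopsy, TABLE2_SLIDES_TOTAL, slide_vals[0], slide_vals[-1], rng
        )

    slides: list[tuple[str, str, str]] = []
    slide_idx = 0
    for bid, k in zip(bio_df["biopsy_id"], per_biopsy):
        for _ in range(k):
            slides.append((f"S{slide_idx:05d}", bid, ""))
            slide_idx += 1

    manifest = CohortManifest(
        patients=pd.DataFrame(patients, columns=["patient_id", "patient_label"]),
        biopsies=bio_df,
        slides=pd.DataFrame(slides, columns=["slide_id", "biopsy_id", "path"]),
    )
    manifest.validate()
    return manifest


# ---------------------------------------------------------------------------
# Tissue-like images
# ---------------------------------------------------------------------------

_BACKGROUND_RGB = np.array([235.0, 233.0, 236.0])
_TISSUE_RGB = np.array([168.0, 96.0, 158.0])  # eosin-ish pink/purple


def generate_tissue_image(
    width: int,
    height: int,
    seed: int = 0,
    blob_fraction: float = 0.3,
    n_blobs: int | None = None,
    noise_sd: float = 5.0,
    rectangles: Sequence[tuple[int, int, int, int]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bright background with darker elliptical tissue blobs.

    Returns ``(image, mask)``: a uint8 RGB image and the boolean ground-truth
    foreground mask.  ``blob_fraction`` targets the foreground pixel fraction
    (stop once reached); ``n_blobs`` instead draws a fixed number of blobs
    (``0`` gives an empty mask).  ``rectangles`` — ``(x0, y0, x1, y1)``
    half-open boxes — overrides random placement; exact footprints are
    useful for constructed-geometry fixtures.
    """
    if width <= 0 or height <= 0:
        raise ValueError("image dimensions must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, _S_IMG]))
    mask = np.zeros((height, width), dtype=bool)

    if rectangles is not None:
        for x0, y0, x1, y1 in rectangles:
            mask[y0:y1, x0:x1] = True
    elif n_blobs is not None:
        for _ in range(n_blobs):
            _add_blob(mask, rng)
    else:
        target = float(blob_fraction)
        for _ in range(10_000):
            if mask.mean() >= target:
                break
            _add_blob(mask, rng)

    img = np.empty((height, width, 3), dtype=np.float64)
    img[:] = _BACKGROUND_RGB
    img[mask] = _TISSUE_RGB
    img += rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), mask


def _add_blob(mask: np.ndarray, rng: np.random.Generator) -> None:
    from skimage.draw import ellipse

    h, w = mask.shape
    scale = min(h, w)
    cy, cx = rng.uniform(0, h), rng.uniform(0, w)
    ry = rng.uniform(0.03, 0.09) * scale
    rx = rng.uniform(0.03, 0.09) * scale
    rr, cc = ellipse(cy, cx, ry, rx, shape=mask.shape, rotation=rng.uniform(0, np.pi))
    mask[rr, cc] = True


# ---------------------------------------------------------------------------
# Embedding bags
# ---------------------------------------------------------------------------


def class_directions(cfg: SyntheticConfig, n: int | None = None) -> np.ndarray:
    """Mutually orthonormal prototype directions, one per class (seeded)."""
    n = len(CLASSES) if n is None else n
    if n > cfg.embed_dim:
        raise ConfigurationError("embed_dim too small for requested directions")
    rng = _rng(cfg.seed, _S_DIRS)
    g = rng.standard_normal((cfg.embed_dim, n))
    q, _ = np.linalg.qr(g)
    return q[:, :n].T  # (n, d)


def background_prototypes(cfg: SyntheticConfig) -> np.ndarray:
    """Shared background tissue-type means: scale x random unit directions.

    Deliberately *not* orthogonalized against the class prototypes — the
    incidental overlap (~1/sqrt(d) per prototype) is what lets slide-level
    composition variation confound mean pooling.
    """
    k = cfg.n_background_types
    if k == 0:
        return np.zeros((0, cfg.embed_dim))
    rng = _rng(cfg.seed, _S_DIRS, 1)
    g = rng.standard_normal((k, cfg.embed_dim))
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    return cfg.background_scale * g


def diagnostic_count(cfg: SyntheticConfig, n_tiles: int) -> int:
    return max(1, int(round(cfg.diag_fraction * n_tiles)))


def square_grid_coords(n_tiles: int) -> np.ndarray:
    """Row-major (row, col) coords on the smallest square-ish grid."""
    ncols = int(np.ceil(np.sqrt(n_tiles)))
    idx = np.arange(n_tiles)
    return np.stack([idx // ncols, idx % ncols], axis=1)


def generate_slide_embeddings(
    cfg: SyntheticConfig, label: str, n_tiles: int, seed: int
) -> tuple[TileEmbeddingMatrix, DiagnosticMask]:
    """Draw one slide's embedding bag and its diagnostic-tile mask.

    Non-benign slides contain a contiguous (row-major) run of diagnostic
    tiles at the class prototype; contiguity gives attention heatmaps and
    region-majority checks a spatially coherent ground truth.
    """
    if label not in CLASSES:
        raise ValueError(f"unknown label {label!r}; expected one of {CLASSES}")
    if n_tiles < 1:
        raise ValueError("n_tiles must be >= 1")
    rng = _rng(cfg.seed, _S_EMB, seed)
    dirs = class_directions(cfg)
    d = cfg.embed_dim
    x = rng.normal(0.0, cfg.noise_sd, size=(n_tiles, d))
    protos = background_prototypes(cfg)
    if len(protos):
        # slide-specific tissue composition over shared background types
        weights = rng.dirichlet(
            np.full(len(protos), cfg.background_dirichlet_alpha)
        )
        assignment = rng.choice(len(protos), size=n_tiles, p=weights)
        x += protos[assignment]
    flags = np.zeros(n_tiles, dtype=bool)
    if label == "Benign":
        x += cfg.delta_benign * dirs[CLASSES.index("Benign")]
    else:
        n_diag = diagnostic_count(cfg, n_tiles)
        start = int(rng.integers(0, n_tiles - n_diag + 1))
        flags[start : start + n_diag] = True
        if len(protos):
            x[flags] -= protos[assignment[flags]]  # diagnostic tissue is its own type
        x[flags] += cfg.class_separation * dirs[CLASSES.index(label)]
    m = TileEmbeddingMatrix(
        slide_id=f"synthetic-{label}-{seed}",
        encoder_name="synthetic",
        matrix=x.astype(np.float32),
        coords=square_grid_coords(n_tiles),
    )
    return m, DiagnosticMask(slide_id=m.slide_id, flags=flags)


def tiles_per_slide(cfg: SyntheticConfig, slide_index: int) -> int:
    """Log-uniform tile count in the configured range (heavy right spread)."""
    lo, hi = cfg.tiles_per_slide_range
    rng = _rng(cfg.seed, _S_TILES, slide_index)
    return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))


def simulate_bags(
    manifest: CohortManifest, cfg: SyntheticConfig
) -> dict[str, tuple[TileEmbeddingMatrix, DiagnosticMask]]:
    """Embedding bags for every slide in a manifest, keyed by slide_id.

    Each slide draws from its own sub-seed, so regenerating one slide never
    perturbs another.
    """
    labels = manifest.slide_labels()
    out: dict[str, tuple[TileEmbeddingMatrix, DiagnosticMask]] = {}
    for i, sid in enumerate(manifest.slides["slide_id"]):
        n = tiles_per_slide(cfg, i)
        m, mask = generate_slide_embeddings(cfg, labels[sid], n, seed=i)
        m.slide_id = mask.slide_id = sid
        out[sid] = (m, mask)
    return out


# ---------------------------------------------------------------------------
# Manifest CSV round trip
# ---------------------------------------------------------------------------


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    """Write patients.csv / biopsies.csv / slides.csv under ``path``."""
    manifest.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest.patients.to_csv(path / "patients.csv", index=False)
    manifest.biopsies.to_csv(path / "biopsies.csv", index=False)
    manifest.slides.to_csv(path / "slides.csv", index=False)


def read_manifest(path: str | Path) -> CohortManifest:
    """Read and validate a manifest directory written by :func:`write_manifest`."""
    path = Path(path)
    kw = dict(dtype=str, keep_default_na=False)
    manifest = CohortManifest(
        patients=pd.read_csv(path / "patients.csv", **kw),
        biopsies=pd.read_csv(path / "biopsies.csv", **kw),
        slides=pd.read_csv(path / "slides.csv", **kw),
    )
    manifest.validate()
    return manifest


# ---------------------------------------------------------------------------
# Annotated slides for the few-shot module
# ---------------------------------------------------------------------------

FEWSHOT_CLASSES: tuple[str, ...] = (
    "invasive_scc",
    "bowen",
    "superficial_bcc",
    "nodular_bcc",
    "epidermis",
    "dermis_subcutis",
    "artifact",
)


@dataclass
class AnnotatedSlide:
    """One synthetic slide with tissue-class bands and their ROI boxes."""

    embeddings: TileEmbeddingMatrix
    rois: list  # list of fewshot.RoiAnnotation
    tile_classes: np.ndarray  # true tissue class per tile, aligned with rows
    grid_shape: tuple[int, int]
    tile_size: int = 256


def generate_annotated_slides(
    cfg: SyntheticConfig,
    classes: Sequence[str] = FEWSHOT_CLASSES,
    n_slides: int = 5,
    grid_side: int = 14,
    seed: int = 0,
) -> list[AnnotatedSlide]:
    """Slides whose tile grid is split into horizontal per-class bands.

    Each band's tiles are drawn at that tissue class's prototype (distance
    ``class_separation`` from the origin, orthogonal directions); one ROI
    bounding box per band covers it exactly.  Emulates a handful of slides
    annotated with quadrangular boxes around tissues of interest.
    """
    from .fewshot import RoiAnnotation

    classes = list(classes)
    if grid_side < len(classes):
        raise ConfigurationError("grid_side must be >= number of classes")
    dirs = class_directions(replace(cfg, seed=cfg.seed + 1), n=len(classes))
    ts = 256
    bounds = np.linspace(0, grid_side, len(classes) + 1).round().astype(int)
    out = []
    for s in range(n_slides):
        rng = _rng(cfg.seed, _S_FEWSHOT, seed, s)
        coords = np.stack(
            np.meshgrid(np.arange(grid_side), np.arange(grid_side), indexing="ij"),
            axis=-1,
        ).reshape(-1, 2)
        tile_classes = np.empty(len(coords), dtype=object)
        x = rng.normal(0.0, cfg.noise_sd, size=(len(coords), cfg.embed_dim))
        rois = []
        sid = f"annotated-{s}"
        for ci, cls in enumerate(classes):
            band = (coords[:, 0] >= bounds[ci]) & (coords[:, 0] < bounds[ci + 1])
            tile_classes[band] = cls
            x[band] += cfg.class_separation * dirs[ci]
            rois.append(
                RoiAnnotation(
                    slide_id=sid,
                    label=cls,
                    x0=0,
                    y0=int(bounds[ci]) * ts,
                    x1=grid_side * ts,
                    y1=int(bounds[ci + 1]) * ts,
                )
            )
        m = TileEmbeddingMatrix(
            slide_id=sid,
            encoder_name="synthetic",
            matrix=x.astype(np.float32),
            coords=coords,
        )
        out.append(
            AnnotatedSlide(
                embeddings=m,
                rois=rois,
                tile_classes=tile_classes,
                grid_shape=(grid_side, grid_side),
                tile_size=ts,
            )
        )
    return out
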