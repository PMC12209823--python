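"""Patient-stratified cross-validation and AUROC-based evaluation.

Folds are assigned at the *patient* level, stratified by patient label, so
no patient's biopsies or slides ever straddle a train/validation boundary —
the leakage guarantee is asserted at runtime, not just at assignment.
Slide-level class probabilities are averaged into biopsy-level
probabilities (labels exist per biopsy), one-vs-rest AUROC is computed per
class and fold (4 classes x 5 folds = 20 values per experiment), and the
summary statistic is the class-proportion-weighted mean AUROC.  Paired
experiments are compared with a one-sided Wilcoxon signed-rank test over
the 20 (class, fold) values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .classify import PROBA_COLUMNS, predict_slide_proba
from .synthetic import CLASSES, CohortManifest

logger = logging.getLogger(__name__)


@dataclass
class FoldAssignment:
    """Patient -> fold mapping, k folds, stratified by patient label."""

    mapping: pd.DataFrame  # patient_id, fold
    k: int

    def fold_of(self) -> dict[str, int]:
        return dict(zip(self.mapping["patient_id"], self.mapping["fold"]))

    def to_csv(self, path) -> None:
        self.mapping.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FoldAssignment":
        df = pd.read_csv(path, dtype={"patient_id": str, "fold": int})
        return cls(mapping=df, k=int(df["fold"].max()) + 1)


@dataclass
class EvalResult:
    """Per-(class, fold) AUROCs plus pooled summaries for one experiment."""

    per_class_fold: pd.DataFrame  # class, fold, auroc (NaN if undefined)
    weighted_mean_auroc: float  # pooled validation predictions
    weighted_mean_auroc_foldavg: float  # mean over folds of per-fold weighted means
    per_class_auroc: dict[str, float]  # pooled, per class
    confusion: np.ndarray  # 4x4, rows = true class
    level: str
    predictions: pd.DataFrame  # pooled validation predictions


def assign_folds(manifest: CohortManifest, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Stratified patient-level fold assignment; deterministic given seed.

    Per-fold patient counts for every class differ from perfect
    stratification by at most one.  Raises if any class has fewer than k
    patients, naming the class.
    """
    patients = manifest.patients
    counts = patients["patient_label"].value_counts()
    for cls in counts.index:
        if counts[cls] < k:
            raise ValueError(
                f"class {cls!r} has only {counts[cls]} patients; need >= {k} for {k} folds"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold = np.empty(len(patients), dtype=int)
    for f, (_, val_idx) in enumerate(
        skf.split(np.zeros(len(patients)), patients["patient_label"])
    ):
        fold[val_idx] = f
    return FoldAssignment(
        mapping=pd.DataFrame({"patient_id": patients["patient_id"], "fold": fold}),
        k=k,
    )


def biopsy_level_probs(slide_preds: pd.DataFrame, manifest: CohortManifest) -> pd.DataFrame:
    """Average slide-level probability vectors within each biopsy.

    The biopsy's label is its manifest label; probability rows remain on
    the simplex because a mean of simplex points is one.
    """
    if len(slide_preds) == 0:
        raise ValueError("no slide predictions to aggregate")
    merged = slide_preds.merge(
        manifest.slides[["slide_id", "biopsy_id"]],
        left_on="unit_id",
        right_on="slide_id",
        how="left",
    )
    if merged["biopsy_id"].isna().any():
        missing = merged.loc[merged["biopsy_id"].isna(), "unit_id"].tolist()
        raise ValueError(f"slides not in manifest: {missing[:5]}")
    bio_labels = manifest.biopsies.set_index("biopsy_id")["biopsy_label"]
    grouped = merged.groupby("biopsy_id", sort=True)[PROBA_COLUMNS].mean().reset_index()
    out = grouped.rename(columns={"biopsy_id": "unit_id"})
    out.insert(1, "level", "biopsy")
    out["label"] = out["unit_id"].map(bio_labels)
    return out


def auroc_one_vs_rest(scores: np.ndarray, labels: np.ndarray) -> float:
    """P(random positive outranks random negative), ties counted one half."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("AUROC undefined: needs both a positive and a negative")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def weighted_mean_auroc(
    per_class_auroc: Sequence[float], class_proportions: Sequence[float]
) -> float:
    """Sum of per-class AUROCs weighted by class proportion."""
    a = np.asarray(per_class_auroc, dtype=float)
    p = np.asarray(class_proportions, dtype=float)
    if a.shape != p.shape:
        raise ValueError("AUROCs and proportions must align")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("class proportions must lie on the simplex")
    return float(np.dot(a, p))


def wilcoxon_one_sided(a: Sequence[float], b: Sequence[float]) -> float:
    """One-sided Wilcoxon signed-rank p-value for the alternative a > b.

    Zero differences are dropped; tied absolute differences get averaged
    ranks.  The null distribution of W+ is exact (dynamic programming over
    signed ranks) for n <= 25 nonzero pairs, and a normal approximation
    with tie correction and continuity correction beyond.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        # integerize (ties give half-integer ranks) and convolve subset sums
        r2 = np.rint(2 * ranks).astype(int)
        total = int(r2.sum())
        ways = np.zeros(total + 1)
        ways[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(ways)
            shifted[r:] = ways[: total + 1 - r]
            ways = ways + shifted
        threshold = int(np.rint(2 * w_plus))
        p = ways[threshold:].sum() / 2.0**n
        return float(p)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    from scipy.stats import norm

    z = (w_plus - mean - 0.5) / np.sqrt(var)
    return float(norm.sf(z))


def compare_experiments(a: "EvalResult", b: "EvalResult") -> float:
    """One-sided Wilcoxon p-value that experiment ``a`` outperforms ``b``.

    Pairs the 20 (class, fold) AUROC entries of the two experiments; pairs
    where either value is undefined are dropped.
    """
    merged = a.per_class_fold.merge(
        b.per_class_fold, on=["class", "fold"], suffixes=("_a", "_b")
    ).dropna()
    return wilcoxon_one_sided(
        merged["auroc_a"].to_numpy(), merged["auroc_b"].to_numpy()
    )


def confusion_matrix(preds: pd.DataFrame) -> np.ndarray:
    """4x4 counts: rows true class, columns argmax-predicted class.

    Argmax ties resolve to the first class in the fixed class order.
    """
    probs = preds[PROBA_COLUMNS].to_numpy()
    pred_idx = np.argmax(probs, axis=1)  # first maximizer = fixed-order tie rule
    true_idx = np.array([CLASSES.index(l) for l in preds["label"]])
    cm = np.zeros((len(CLASSES), len(CLASSES)), dtype=int)
    np.add.at(cm, (true_idx, pred_idx), 1)
    return cm


# ---------------------------------------------------------------------------
# Cross-validation harness
# ---------------------------------------------------------------------------


def _slide_fold_frame(manifest: CohortManifest, folds: FoldAssignment) -> pd.DataFrame:
    df = manifest.slides.merge(manifest.biopsies, on="biopsy_id")
    df = df.merge(folds.mapping, on="patient_id")
    return df  # slide_id, biopsy_id, patient_id, biopsy_label, fold


def run_cross_validation(
    manifest: CohortManifest,
    bags: Mapping[str, object],
    fit_predict: Callable,
    folds: FoldAssignment,
    level: str = "biopsy",
) -> EvalResult:
    """Train on k-1 folds, score the held-out fold, aggregate, and summarize.

    ``bags`` maps slide_id to that slide's feature object (an embedding
    vector or a tile-embedding bag).  ``fit_predict(train_feats,
    train_labels, val_feats) -> (n_val, 4) probabilities`` encapsulates the
    aggregator/classifier pipeline; it is called once per fold.

    Per fold and class, one-vs-rest AUROC is computed on the held-out
    predictions at the requested level; a fold missing a class records NaN
    with a warning and is excluded from summaries.  The weighted mean AUROC
    uses pooled validation predictions and class proportions of the
    evaluated units.
    """
    sf = _slide_fold_frame(manifest, folds)
    pooled = []
    for f in range(folds.k):
        train = sf[sf["fold"] != f]
        val = sf[sf["fold"] == f]
        # runtime leakage assertion
        overlap = set(train["patient_id"]) & set(val["patient_id"])
        if overlap:
            raise AssertionError(f"patient leakage across folds: {sorted(overlap)[:3]}")
        probs = fit_predict(
            [bags[s] for s in train["slide_id"]],
            train["biopsy_label"].to_numpy(),
            [bags[s] for s in val["slide_id"]],
        )
        preds = predict_slide_proba(
            _Precomputed(probs), None, val["slide_id"], val["biopsy_label"], level="slide"
        )
        unit_preds = biopsy_level_probs(preds, manifest) if level == "biopsy" else preds
        unit_preds = unit_preds.copy()
        unit_preds["fold"] = f
        pooled.append(unit_preds)
    pooled_df = pd.concat(pooled, ignore_index=True)
    return summarize_predictions(pooled_df, k=folds.k, level=level)


def summarize_predictions(pooled_df: pd.DataFrame, k: int, level: str = "biopsy") -> EvalResult:
    """Assemble the 20-entry (class, fold) AUROC table and pooled summaries.

    ``pooled_df`` holds validation predictions from every fold, with a
    ``fold`` column.  Folds missing a class record NaN (with a warning) and
    drop out of the weighted means, whose class proportions are renormalized
    over the remaining classes.
    """
    rows = []
    for f in range(k):
        fold_df = pooled_df[pooled_df["fold"] == f]
        for ci, cls in enumerate(CLASSES):
            pos = (fold_df["label"] == cls).to_numpy()
            if pos.all() or not pos.any():
                logger.warning("fold %d has no %s in validation; AUROC undefined", f, cls)
                rows.append((cls, f, np.nan))
                continue
            auroc = auroc_one_vs_rest(fold_df[PROBA_COLUMNS[ci]].to_numpy(), pos)
            rows.append((cls, f, auroc))
    per_cf = pd.DataFrame(rows, columns=["class", "fold", "auroc"])

    per_class_pooled = {}
    for ci, cls in enumerate(CLASSES):
        pos = (pooled_df["label"] == cls).to_numpy()
        per_class_pooled[cls] = (
            auroc_one_vs_rest(pooled_df[PROBA_COLUMNS[ci]].to_numpy(), pos)
            if pos.any() and not pos.all()
            else np.nan
        )

    props = np.array([(pooled_df["label"] == c).mean() for c in CLASSES])
    valid = ~np.isnan([per_class_pooled[c] for c in CLASSES])
    p_norm = np.where(valid, props, 0.0)
    p_norm = p_norm / p_norm.sum()
    wm_pooled = float(
        np.nansum(p_norm * np.array([per_class_pooled[c] for c in CLASSES]))
    )

    # per-fold weighted means, then averaged across folds
    fold_means = []
    for f in range(k):
        sub = per_cf[per_cf["fold"] == f]
        fold_df = pooled_df[pooled_df["fold"] == f]
        aur = sub.set_index("class")["auroc"]
        fp = np.array([(fold_df["label"] == c).mean() for c in CLASSES])
        ok = ~aur.reindex(list(CLASSES)).isna().to_numpy()
        if fp[ok].sum() == 0:
            continue
        fp = np.where(ok, fp, 0.0)
        fp = fp / fp.sum()
        fold_means.append(float(np.nansum(fp * aur.reindex(list(CLASSES)).to_numpy())))
    wm_foldavg = float(np.mean(fold_means)) if fold_means else float("nan")

    return EvalResult(
        per_class_fold=per_cf,
        weighted_mean_auroc=wm_pooled,
        weighted_mean_auroc_foldavg=wm_foldavg,
        per_class_auroc=per_class_pooled,
        confusion=confusion_matrix(pooled_df),
        level=level,
        predictions=pooled_df,
    )


class _Precomputed:
    """Adapter exposing fixed probabilities through the classifier protocol."""

    def __init__(self, probs: np.ndarray):
        self._probs = np.asarray(probs)
        self.classes_ = np.asarray(CLASSES)

    def predict_proba(self, X):
        return self._probs
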