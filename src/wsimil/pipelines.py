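"""Aggregator + classifier pipeline specs pluggable into cross-validation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import (
    AbmilMlpClassifier,
    BoostedTreesClassifier,
    LinearSoftmaxClassifier,
    MlpClassifier,
    TrainConfig,
)
from .embedding import TileEmbeddingMatrix
from .synthetic import CLASSES

AGGREGATORS = ("gap", "abmil")
CLASSIFIERS = ("lr", "gbt", "mlp")


@dataclass(frozen=True)
class PipelineSpec:
    """One experiment arm: how bags become slide embeddings and predictions.

    ``aggregator='abmil'`` trains the attention module jointly with an MLP
    head, so the classifier field is ignored in that arm.
    """

    aggregator: str = "gap"
    classifier: str = "lr"
    gated: bool = False
    n_branches: int = 1
    use_positional: bool = True
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.aggregator not in AGGREGATORS:
            raise ValueError(f"unknown aggregator {self.aggregator!r}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")

    @property
    def name(self) -> str:
        return (
            f"abmil+mlp" if self.aggregator == "abmil" else f"gap+{self.classifier}"
        )


def _gap_matrix(bags: list[TileEmbeddingMatrix]) -> np.ndarray:
    return np.stack([b.matrix.astype(np.float64).mean(axis=0) for b in bags])


def _reorder(probs: np.ndarray, classes: np.ndarray) -> np.ndarray:
    out = np.zeros((probs.shape[0], len(CLASSES)))
    for j, cls in enumerate(classes):
        out[:, CLASSES.index(cls)] = probs[:, j]
    return out


def fit_predict_fn(spec: PipelineSpec):
    """Callable (train_bags, train_labels, val_bags) -> (n_val, 4) probabilities.

    Probability columns follow the fixed class order Benign, Bowen, BCC, SCC.
    """
    cfg = spec.train

    def _run(train_bags, y_train, val_bags):
        if spec.aggregator == "abmil":
            model = AbmilMlpClassifier(
                gated=spec.gated,
                n_branches=spec.n_branches,
                use_positional=spec.use_positional,
                max_epochs=cfg.max_epochs,
                grad_accum_slides=cfg.grad_accum_slides,
                learning_rate=cfg.learning_rate,
                weight_decay=cfg.weight_decay,
                step_budget=cfg.step_budget,
                random_state=cfg.seed,
            ).fit(train_bags, y_train)
            return _reorder(model.predict_proba(val_bags), model.classes_)
        X_train = _gap_matrix(train_bags)
        X_val = _gap_matrix(val_bags)
        if spec.classifier == "lr":
            model = LinearSoftmaxClassifier(random_state=cfg.seed).fit(X_train, y_train)
        elif spec.classifier == "gbt":
            model = BoostedTreesClassifier(random_state=cfg.seed).fit(X_train, y_train)
        else:
            model = MlpClassifier(
                max_epochs=cfg.max_epochs,
                grad_accum_slides=cfg.grad_accum_slides,
                learning_rate=cfg.learning_rate,
                weight_decay=cfg.weight_decay,
                step_budget=cfg.step_budget,
                dropout=cfg.dropout,
                random_state=cfg.seed,
            ).fit(X_train, y_train)
        return _reorder(model.predict_proba(X_val), model.classes_)

    return _run


def evaluate_pipeline(manifest, bags, spec: PipelineSpec, folds, level: str = "biopsy"):
    """Run the full cross-validated evaluation of one pipeline spec."""
    from .evaluate import run_cross_validation

    only_bags = {sid: pair[0] if isinstance(pair, tuple) else pair for sid, pair in bags.items()}
    return run_cross_validation(manifest, only_bags, fit_predict_fn(spec), folds, level=level)
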