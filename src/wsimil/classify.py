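"""Slide-level classifiers over fixed embeddings, and joint ABMIL + MLP training.

Three probabilistic classifiers operate on precomputed slide embeddings,
used exactly as produced (no normalization or other transform):

* :class:`LinearSoftmaxClassifier` — multinomial logistic regression
  (SAGA solver, L2 penalty, 1,000 max iterations);
* :class:`BoostedTreesClassifier` — gradient-boosted trees with library
  defaults and a softmax objective;
* :class:`MlpClassifier` — a feedforward network with three hidden layers
  (1024, 512, 256) and a 4-way output, trained with AdamW on cross-entropy.

:class:`AbmilMlpClassifier` trains the attention aggregator end to end with
the MLP head over tile-embedding bags: one slide per forward pass,
gradients accumulated over ``grad_accum_slides`` slides per optimizer step.

Training recipe defaults follow the reference protocol: at most 30 epochs,
gradient accumulation over 16 slides, learning rate 1e-5, AdamW,
cross-entropy loss.  Because step count rather than epoch count governs
convergence at a fixed learning rate, a ``step_budget`` (default 3,200 —
the optimizer-step count the 30-epoch recipe implies at full cohort scale)
extends the epoch count on small cohorts; at full scale it is inactive and
the recipe is exactly the 30-epoch one.  All estimators follow the
scikit-learn fit/predict_proba contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import LabelEncoder

from ._nn import AdamW, cross_entropy, init_mlp, mlp_backward, mlp_forward, softmax_rows
from .aggregation import (
    AbmilParams,
    AttentionRecord,
    abmil_backward,
    abmil_forward,
    positional_embedding_grid,
)
from .embedding import TileEmbeddingMatrix
from .synthetic import CLASSES

logger = logging.getLogger(__name__)

PROBA_COLUMNS = ["p_benign", "p_bowen", "p_bcc", "p_scc"]
DEFAULT_HIDDEN_DIMS = (1024, 512, 256)
DEFAULT_STEP_BUDGET = 3200  # ~30 epochs x (2,130 slides * 4/5) / 16 per step


@dataclass(frozen=True)
class TrainConfig:
    """Deep-model training recipe (AdamW over cross-entropy)."""

    max_epochs: int = 30
    grad_accum_slides: int = 16
    learning_rate: float = 1e-5
    weight_decay: float = 1e-2
    step_budget: int | None = DEFAULT_STEP_BUDGET
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 0 or self.grad_accum_slides < 1 or self.learning_rate <= 0:
            raise ValueError("epochs must be >= 0, accumulation and learning rate positive")

    def n_epochs(self, n_units: int) -> int:
        """Epochs to run for a training set of ``n_units`` slides."""
        if self.max_epochs == 0:
            return 0
        steps_per_epoch = max(1, int(np.ceil(n_units / self.grad_accum_slides)))
        epochs = self.max_epochs
        if self.step_budget is not None:
            epochs = max(epochs, int(np.ceil(self.step_budget / steps_per_epoch)))
        return epochs


@dataclass(frozen=True)
class MlpSpec:
    """Three hidden layers (1024, 512, 256) and a 4-way classification layer."""

    hidden_dims: tuple[int, ...] = DEFAULT_HIDDEN_DIMS
    n_classes: int = 4
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if len(self.hidden_dims) != 3:
            raise ValueError("spec requires exactly three hidden layers")


def _check_training_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    return y


# ---------------------------------------------------------------------------
# Classifiers over fixed slide embeddings
# ---------------------------------------------------------------------------


class LinearSoftmaxClassifier(BaseEstimator, ClassifierMixin):
    """Multinomial softmax regression (SAGA, L2, 1,000 max iterations)."""

    def __init__(self, C: float = 1.0, max_iter: int = 1000, random_state: int = 0):
        self.C = C
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X)
        y = _check_training_labels(y)
        # L2 regularization is sklearn's default penalty
        self.model_ = LogisticRegression(
            solver="saga",
            C=self.C,
            max_iter=self.max_iter,
            random_state=self.random_state,
        )
        import warnings
        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.model_.fit(X, y)
        self.classes_ = self.model_.classes_
        return self

    def predict_proba(self, X):
        return self.model_.predict_proba(np.asarray(X))

    def predict(self, X):
        return self.model_.predict(np.asarray(X))


class BoostedTreesClassifier(BaseEstimator, ClassifierMixin):
    """Gradient-boosted decision trees, library defaults, softmax objective."""

    def __init__(self, random_state: int = 0):
        self.random_state = random_state

    def fit(self, X, y):
        from xgboost import XGBClassifier

        X = np.asarray(X)
        y = _check_training_labels(y)
        self._encoder_ = LabelEncoder().fit(y)
        # softmax objective for the multiclass task; xgboost picks the
        # binary logistic objective itself when only two classes appear
        kwargs = {}
        if len(self._encoder_.classes_) > 2:
            kwargs["objective"] = "multi:softprob"
        self.model_ = XGBClassifier(
            random_state=self.random_state,
            n_jobs=1,
            **kwargs,
        )
        self.model_.fit(X, self._encoder_.transform(y))
        self.classes_ = self._encoder_.classes_
        return self

    def predict_proba(self, X):
        return self.model_.predict_proba(np.asarray(X))

    def predict(self, X):
        idx = np.argmax(self.predict_proba(X), axis=1)
        return self.classes_[idx]


class MlpClassifier(BaseEstimator, ClassifierMixin):
    """Three-hidden-layer MLP trained with AdamW over cross-entropy.

    Layer shapes for input dim d are d -> 1024 -> 512 -> 256 -> n_classes.
    ReLU activations, no dropout by default.  The final layer starts at
    zero, so a model trained for zero epochs predicts uniformly.
    """

    def __init__(
        self,
        hidden_dims: tuple[int, ...] = DEFAULT_HIDDEN_DIMS,
        max_epochs: int = 30,
        grad_accum_slides: int = 16,
        learning_rate: float = 1e-5,
        weight_decay: float = 1e-2,
        step_budget: int | None = DEFAULT_STEP_BUDGET,
        dropout: float = 0.0,
        random_state: int = 0,
    ):
        self.hidden_dims = hidden_dims
        self.max_epochs = max_epochs
        self.grad_accum_slides = grad_accum_slides
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.step_budget = step_budget
        self.dropout = dropout
        self.random_state = random_state

    def _config(self) -> TrainConfig:
        return TrainConfig(
            max_epochs=self.max_epochs,
            grad_accum_slides=self.grad_accum_slides,
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            step_budget=self.step_budget,
            dropout=self.dropout,
            seed=self.random_state,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        y = _check_training_labels(y)
        self.classes_ = np.unique(y)
        y_idx = np.searchsorted(self.classes_, y)
        dims = (X.shape[1], *self.hidden_dims, len(self.classes_))
        self.layers_ = init_mlp(dims, seed=self.random_state, dtype=np.float32)
        cfg = self._config()
        params = {}
        for i, (W, b) in enumerate(self.layers_):
            params[f"W{i}"] = W
            params[f"b{i}"] = b
        opt = AdamW(
            params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay
        )
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x51EE]))
        n = X.shape[0]
        n_epochs = cfg.n_epochs(n)
        drop_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xD0]))
        self.loss_curve_ = []
        self.n_steps_ = 0
        for _ in range(n_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.grad_accum_slides):
                chunk = order[start : start + cfg.grad_accum_slides]
                logits, acts = mlp_forward(
                    self.layers_, X[chunk], return_cache=True
                )
                if self.dropout > 0.0:
                    acts = self._apply_dropout(acts, drop_rng)
                    logits = acts[-1]
                loss, dlogits = cross_entropy(logits, y_idx[chunk])
                grads, _ = mlp_backward(self.layers_, acts, dlogits)
                gdict = {}
                for i, (dW, db) in enumerate(grads):
                    gdict[f"W{i}"] = dW
                    gdict[f"b{i}"] = db
                opt.step(gdict)
                self.n_steps_ += 1
                losses.append(loss)
            self.loss_curve_.append(float(np.mean(losses)))
        return self

    def _apply_dropout(self, acts, rng):
        # inverted dropout on hidden activations; final logits recomputed
        kept = [acts[0]]
        a = acts[0]
        for i, (W, b) in enumerate(self.layers_):
            z = a @ W.T + b
            if i < len(self.layers_) - 1:
                a = np.maximum(z, 0.0)
                mask = rng.random(a.shape) >= self.dropout
                a = a * mask / (1.0 - self.dropout)
            else:
                a = z
            kept.append(a)
        return kept

    def predict_proba(self, X):
        if not hasattr(self, "layers_"):
            raise NotFittedError("MlpClassifier is not fitted")
        X = np.asarray(X, dtype=np.float32)
        if X.shape[1] != self.layers_[0][0].shape[1]:
            raise ValueError(
                f"input dim {X.shape[1]} != training dim {self.layers_[0][0].shape[1]}"
            )
        return softmax_rows(mlp_forward(self.layers_, X).astype(np.float64))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# ---------------------------------------------------------------------------
# Joint ABMIL + MLP
# ---------------------------------------------------------------------------


def _as_bag(bag) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(bag, TileEmbeddingMatrix):
        return bag.matrix, bag.coords
    x, coords = bag
    return np.asarray(x), np.asarray(coords)


class AbmilMlpClassifier(BaseEstimator, ClassifierMixin):
    """Attention-MIL aggregator trained jointly with an MLP head.

    ``fit`` takes a sequence of bags — :class:`TileEmbeddingMatrix` objects
    or ``(matrix, coords)`` pairs — and slide labels.  Each forward pass
    processes one slide; gradients are accumulated over
    ``grad_accum_slides`` slides (loss averaged within the accumulation
    window) before each AdamW step.  Both the aggregator and the head are
    updated; tile embeddings themselves are frozen inputs.

    Unlike the standalone MLP, the head's output layer uses fan-in
    initialization: a zero-initialized head would pass no gradient to the
    attention module early in training, crippling attention bootstrap
    under the small fixed learning rate.
    """

    def __init__(
        self,
        attention_hidden_dim: int = 128,
        n_branches: int = 1,
        gated: bool = False,
        use_positional: bool = True,
        hidden_dims: tuple[int, ...] = DEFAULT_HIDDEN_DIMS,
        max_epochs: int = 30,
        grad_accum_slides: int = 16,
        learning_rate: float = 1e-5,
        weight_decay: float = 1e-2,
        step_budget: int | None = DEFAULT_STEP_BUDGET,
        random_state: int = 0,
    ):
        self.attention_hidden_dim = attention_hidden_dim
        self.n_branches = n_branches
        self.gated = gated
        self.use_positional = use_positional
        self.hidden_dims = hidden_dims
        self.max_epochs = max_epochs
        self.grad_accum_slides = grad_accum_slides
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.step_budget = step_budget
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _prepare(self, bag) -> np.ndarray:
        x, coords = _as_bag(bag)
        H = x.astype(np.float32)
        if self.use_positional:
            H = H + positional_embedding_grid(coords, H.shape[1]).astype(np.float32)
        return H

    def fit(self, bags: Sequence, y):
        y = _check_training_labels(y)
        bags = list(bags)
        if len(bags) != len(y):
            raise ValueError("bags and labels must have equal length")
        H_all = [self._prepare(b) for b in bags]
        if any(h.shape[0] < 1 for h in H_all):
            raise ValueError("every bag must be non-empty")
        d = H_all[0].shape[1]
        self.classes_ = np.unique(y)
        y_idx = np.searchsorted(self.classes_, y)

        self.abmil_ = AbmilParams.init(
            d,
            hidden_dim=self.attention_hidden_dim,
            n_branches=self.n_branches,
            gated=self.gated,
            seed=self.random_state,
            dtype=np.float32,
        )
        # fan-in init everywhere: a zero output layer would block gradient
        # flow into the aggregator for the first hundreds of steps
        self.layers_ = init_mlp(
            (d, *self.hidden_dims, len(self.classes_)),
            seed=self.random_state,
            zero_final=False,
            dtype=np.float32,
        )
        params = {f"a_{k}": v for k, v in self.abmil_.as_dict().items()}
        for i, (W, b) in enumerate(self.layers_):
            params[f"m_W{i}"] = W
            params[f"m_b{i}"] = b
        cfg = TrainConfig(
            max_epochs=self.max_epochs,
            grad_accum_slides=self.grad_accum_slides,
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            step_budget=self.step_budget,
            seed=self.random_state,
        )
        opt = AdamW(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xAB41]))
        n = len(bags)
        n_epochs = cfg.n_epochs(n)
        self.loss_curve_ = []
        self.n_steps_ = 0
        for epoch in range(n_epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, cfg.grad_accum_slides):
                chunk = order[start : start + cfg.grad_accum_slides]
                # per-slide ABMIL forwards, then one batched pass through the
                # MLP head (gradients identical to slide-at-a-time accumulation
                # with the loss averaged over the window)
                caches = []
                S = np.empty((len(chunk), d), dtype=np.float32)
                for j, idx in enumerate(chunk):
                    s, _, cache = abmil_forward(
                        H_all[idx], self.abmil_, return_cache=True
                    )
                    S[j] = s
                    caches.append(cache)
                logits, acts = mlp_forward(self.layers_, S, return_cache=True)
                loss, dlogits = cross_entropy(logits, y_idx[chunk])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"NaN loss at epoch {epoch}, slide indices {chunk.tolist()}"
                    )
                mlp_grads, dS = mlp_backward(self.layers_, acts, dlogits)
                accum = {}
                for i, (dW, db) in enumerate(mlp_grads):
                    accum[f"m_W{i}"] = dW
                    accum[f"m_b{i}"] = db
                for j, idx in enumerate(chunk):
                    for k, g in abmil_backward(dS[j], self.abmil_, caches[j]).items():
                        key = f"a_{k}"
                        if key in accum:
                            accum[key] += g
                        else:
                            accum[key] = g
                opt.step(accum)
                self.n_steps_ += 1
                epoch_losses.append(loss)
            self.loss_curve_.append(float(np.mean(epoch_losses)))
        return self

    def predict_proba(self, bags: Sequence) -> np.ndarray:
        if not hasattr(self, "abmil_"):
            raise NotFittedError("AbmilMlpClassifier is not fitted")
        out = []
        for bag in bags:
            H = self._prepare(bag)
            if H.shape[1] != self.abmil_.dim:
                raise ValueError(
                    f"bag dim {H.shape[1]} != training dim {self.abmil_.dim}"
                )
            s, _ = abmil_forward(H, self.abmil_)
            logits = mlp_forward(self.layers_, s[None, :])
            out.append(softmax_rows(logits.astype(np.float64))[0])
        return np.asarray(out) if out else np.zeros((0, len(self.classes_)))

    def predict(self, bags: Sequence):
        return self.classes_[np.argmax(self.predict_proba(bags), axis=1)]

    def attention(self, bag) -> AttentionRecord:
        """Softmax attention weights of a fitted model over one bag."""
        if not hasattr(self, "abmil_"):
            raise NotFittedError("AbmilMlpClassifier is not fitted")
        x, coords = _as_bag(bag)
        H = self._prepare(bag)
        _, A = abmil_forward(H, self.abmil_)
        sid = bag.slide_id if isinstance(bag, TileEmbeddingMatrix) else "bag"
        return AttentionRecord(slide_id=sid, weights=A, coords=coords)


# ---------------------------------------------------------------------------
# Thin functional wrappers and prediction tables
# ---------------------------------------------------------------------------


def train_linear_softmax(X, y, seed: int = 0) -> LinearSoftmaxClassifier:
    return LinearSoftmaxClassifier(random_state=seed).fit(X, y)


def train_boosted_trees(X, y, seed: int = 0) -> BoostedTreesClassifier:
    return BoostedTreesClassifier(random_state=seed).fit(X, y)


def train_mlp(X, y, cfg: TrainConfig | None = None, spec: MlpSpec | None = None) -> MlpClassifier:
    cfg = cfg or TrainConfig()
    spec = spec or MlpSpec()
    return MlpClassifier(
        hidden_dims=spec.hidden_dims,
        max_epochs=cfg.max_epochs,
        grad_accum_slides=cfg.grad_accum_slides,
        learning_rate=cfg.learning_rate,
        weight_decay=cfg.weight_decay,
        step_budget=cfg.step_budget,
        dropout=spec.dropout,
        random_state=cfg.seed,
    ).fit(X, y)


def train_abmil_mlp(
    bags,
    y,
    cfg: TrainConfig | None = None,
    gated: bool = False,
    n_branches: int = 1,
    use_positional: bool = True,
) -> AbmilMlpClassifier:
    cfg = cfg or TrainConfig()
    return AbmilMlpClassifier(
        gated=gated,
        n_branches=n_branches,
        use_positional=use_positional,
        max_epochs=cfg.max_epochs,
        grad_accum_slides=cfg.grad_accum_slides,
        learning_rate=cfg.learning_rate,
        weight_decay=cfg.weight_decay,
        step_budget=cfg.step_budget,
        random_state=cfg.seed,
    ).fit(bags, y)


def predict_slide_proba(
    model, X_or_bags, unit_ids: Sequence[str], labels: Sequence[str], level: str = "slide"
) -> pd.DataFrame:
    """Per-unit class probabilities as a prediction table.

    Columns: unit_id, level, p_benign..p_scc (fixed class order), label.
    Probability columns for classes absent from training are zero.
    """
    unit_ids = list(unit_ids)
    labels = list(labels)
    table = pd.DataFrame(columns=["unit_id", "level", *PROBA_COLUMNS, "label"])
    if len(unit_ids) == 0:
        return table
    raw = model.predict_proba(X_or_bags)
    probs = np.zeros((raw.shape[0], len(CLASSES)))
    for j, cls in enumerate(model.classes_):
        probs[:, CLASSES.index(cls)] = raw[:, j]
    table = pd.DataFrame(probs, columns=PROBA_COLUMNS)
    table.insert(0, "unit_id", unit_ids)
    table.insert(1, "level", level)
    table["label"] = labels
    _validate_prediction_table(table)
    return table


def _validate_prediction_table(table: pd.DataFrame) -> None:
    probs = table[PROBA_COLUMNS].to_numpy()
    if np.any(probs < -1e-9) or np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("prediction rows must be probability simplices")
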