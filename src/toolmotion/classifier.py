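"""Tool classification from hand-motion sequences.

The model is an LSTM over per-frame 128-d visual features followed by a
one-hidden-layer MLP with a single sigmoid unit applied at every timestep,
trained with class-weighted binary cross-entropy (Adam, learning rate 1e-3,
batch size 5, dropout 0.5, random T-frame fragment sampling per epoch).
Scissors are coded as the positive class; needle holders as negative.

The API follows the fitted-model idiom: ``SequenceToolClassifier`` is built
from feature sequences and labels, ``fit()`` returns a
``SequenceClassifierResults`` carrying the trained parameters, loss history
and prediction/evaluation methods, and ``summary()`` renders a readable
table.  ``PerFrameBaseline`` trains the identical head on single-frame
features without the recurrent aggregator, quantifying how much of the
signal is appearance rather than motion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .features import FEATURE_DIM
from .metrics import ConfusionCounts, prf_metrics
from .sequencing import DEFAULT_T

POSITIVE_CLASS = "scissors"
NEGATIVE_CLASS = "needle_holders"
CLASS_TO_INT = {NEGATIVE_CLASS: 0, POSITIVE_CLASS: 1}
INT_TO_CLASS = {v: k for k, v in CLASS_TO_INT.items()}

FUSIONS = ("mean", "last", "max")


@dataclass
class ClassifierConfig:
    """Training hyperparameters.

    Defaults: 2 s windows at 25 fps (T=50), 128-d features, 128-d LSTM
    hidden state with tanh activation, one 64-unit ReLU hidden layer in the
    head, dropout 0.5 on the head input, Adam at 1e-3, batch size 5,
    15 epochs.
    """

    T: int = DEFAULT_T
    feature_dim: int = FEATURE_DIM
    recurrent_hidden: int = 128
    head_hidden: int = 64
    dropout: float = 0.5
    learning_rate: float = 1.0e-3
    batch_size: int = 5
    epochs: int = 15
    class_weights: tuple[float, float] | None = None  # (w_neg, w_pos); None -> inverse frequency
    fusion: str = "mean"
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fusion not in FUSIONS:
            raise ValueError(f"fusion must be one of {FUSIONS}")
        if self.class_weights is not None and min(self.class_weights) <= 0:
            raise ValueError("class weights must be positive")


@dataclass
class Prediction:
    """Per-timestep probabilities, their fusion, and the decoded label."""

    p_t: np.ndarray
    p_final: float
    label: str


def compute_class_weights(counts: dict[str, int]) -> dict[str, float]:
    """Inverse-frequency weights w_c = N / (K * n_c).

    The count-weighted mean of the weights is 1, so the loss scale is
    comparable to the unweighted case.  Zero counts are rejected.
    """
    if any(c <= 0 for c in counts.values()):
        raise ValueError("all class counts must be positive")
    total = sum(counts.values())
    k = len(counts)
    return {cls: total / (k * n) for cls, n in counts.items()}


def weighted_ce(
    p_t: np.ndarray, y: int, class_weights: tuple[float, float] = (1.0, 1.0)
) -> float:
    """Weighted cross-entropy of one sequence's per-timestep probabilities."""
    if y not in (0, 1):
        raise ValueError("y must be 0 or 1")
    return nn.weighted_bce(np.asarray(p_t, dtype=float), np.array([y]), class_weights)


def sequence_label(p_t: np.ndarray, fusion: str = "mean") -> tuple[float, str]:
    """Fuse per-timestep probabilities into one decision.

    mean (default): arithmetic mean of p_t; last: p_T; max: max_t p_t.
    The label is the positive class iff the fused probability is >= 0.5.
    """
    p_t = np.asarray(p_t, dtype=float)
    if p_t.size < 1:
        raise ValueError("need at least one timestep")
    if fusion == "mean":
        p_final = float(p_t.mean())
    elif fusion == "last":
        p_final = float(p_t[-1])
    elif fusion == "max":
        p_final = float(p_t.max())
    else:
        raise ValueError(f"fusion must be one of {FUSIONS}")
    return p_final, INT_TO_CLASS[int(p_final >= 0.5)]


def _standardize(psi: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    return (psi - mean) / std


def _labels_to_int(labels) -> np.ndarray:
    out = []
    for lab in labels:
        if isinstance(lab, str):
            out.append(CLASS_TO_INT[lab])
        else:
            out.append(int(lab))
    return np.asarray(out, dtype=int)


class _NetworkMixin:
    """Shared forward/training loop machinery for the two models."""

    def _forward(self, X: np.ndarray, train: bool, rng=None) -> np.ndarray:
        raise NotImplementedError

    def _modules(self) -> list:
        raise NotImplementedError

    def _loss_and_grads(self, X, y, class_weights, rng):
        p = self._forward(X, train=True, rng=rng)
        loss = nn.weighted_bce(p, y, class_weights)
        dz = nn.weighted_bce_logit_grad(p, y, class_weights)
        grads = self._backward(dz)
        return loss, grads

    def _apply_step(self, optimizer, grads, clip):
        nn.clip_gradients(grads, clip)
        params = {}
        for name, mod in self._modules():
            for key, val in mod.params().items():
                params[f"{name}.{key}"] = val
        optimizer.step(params, grads)


class SequenceToolClassifier(_NetworkMixin):
    """LSTM + per-timestep MLP classifier over fixed-length feature clips.

    Parameters
    ----------
    features : list of (T, d) arrays or (N, T, d) array
        Per-frame visual features of each training clip.  Clips longer than
        ``config.T`` are subsampled by random fragment each epoch.
    labels : sequence of str or {0, 1}
        Tool class per clip ("scissors" positive, "needle_holders" negative).
    config : ClassifierConfig
    """

    def __init__(self, features, labels, config: ClassifierConfig | None = None):
        self.config = config or ClassifierConfig()
        self.features = [np.asarray(f, dtype=float) for f in features]
        self.y = _labels_to_int(labels)
        if len(self.features) != len(self.y):
            raise ValueError("features and labels length mismatch")
        classes = np.unique(self.y)
        if len(self.features) and len(classes) < 2:
            raise ValueError("training set must contain both classes")
        for f in self.features:
            if f.ndim != 2 or f.shape[1] != self.config.feature_dim:
                raise ValueError(
                    f"each clip must be (T, {self.config.feature_dim}); got {f.shape}"
                )
            if f.shape[0] < self.config.T:
                raise ValueError(f"clip shorter than T={self.config.T}")
        self._rng = np.random.default_rng(self.config.seed)
        cfg = self.config
        self.lstm = nn.LSTM(cfg.feature_dim, cfg.recurrent_hidden, self._rng)
        self.head = nn.MLPHead(cfg.recurrent_hidden, cfg.head_hidden, self._rng)
        self.drop = nn.Dropout(cfg.dropout)
        stacked = np.concatenate(self.features, axis=0)
        self.feat_mean = stacked.mean(axis=0)
        self.feat_std = stacked.std(axis=0) + 1e-8

    # -- network ---------------------------------------------------------

    def _modules(self):
        return [("lstm", self.lstm), ("head", self.head)]

    def _forward(self, X, train=False, rng=None):
        Hs = self.lstm.forward(X, train=train)
        Hd = self.drop.forward(Hs, rng or self._rng, train)
        return self.head.forward(Hd, train=train)

    def _backward(self, dz):
        head_grads, dH = self.head.backward(dz)
        dH = self.drop.backward(dH)
        lstm_grads, _ = self.lstm.backward(dH)
        grads = {f"head.{k}": v for k, v in head_grads.items()}
        grads.update({f"lstm.{k}": v for k, v in lstm_grads.items()})
        return grads

    def aggregate_sequence(self, psi: np.ndarray) -> np.ndarray:
        """Causal recurrent aggregation: psi (T, d) -> psi_hat (T, H)."""
        X = _standardize(np.asarray(psi, float), self.feat_mean, self.feat_std)
        return self.lstm.forward(X[None])[0]

    def predict_timesteps(self, psi_hat: np.ndarray) -> np.ndarray:
        """Per-timestep probabilities from aggregated features (T, H) -> (T,)."""
        return self.head.forward(np.asarray(psi_hat, float)[None])[0]

    # -- fitting ---------------------------------------------------------

    def fit(self, epochs: int | None = None) -> "SequenceClassifierResults":
        cfg = self.config
        n_epochs = cfg.epochs if epochs is None else epochs
        if cfg.class_weights is not None:
            weights = cfg.class_weights
        else:
            counts = {
                NEGATIVE_CLASS: int((self.y == 0).sum()),
                POSITIVE_CLASS: int((self.y == 1).sum()),
            }
            w = compute_class_weights(counts)
            weights = (w[NEGATIVE_CLASS], w[POSITIVE_CLASS])
        optimizer = nn.Adam(lr=cfg.learning_rate)
        n = len(self.features)
        loss_history: list[float] = []
        for _epoch in range(n_epochs):
            order = self._rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                X = np.stack([self._fragment(self.features[i]) for i in idx])
                X = _standardize(X, self.feat_mean, self.feat_std)
                y = self.y[idx]
                loss, grads = self._loss_and_grads(X, y, weights, self._rng)
                self._apply_step(optimizer, grads, cfg.grad_clip)
                epoch_loss += loss
                n_batches += 1
            loss_history.append(epoch_loss / max(n_batches, 1))
        return SequenceClassifierResults(self, loss_history, weights)

    def _fragment(self, f: np.ndarray) -> np.ndarray:
        T = self.config.T
        if f.shape[0] == T:
            return f
        off = int(self._rng.integers(f.shape[0] - T + 1))
        return f[off : off + T]


@dataclass
class SequenceClassifierResults:
    """Fitted sequence classifier: loss history, predictions, metrics."""

    model: SequenceToolClassifier
    loss_history: list[float]
    class_weights: tuple[float, float]

    def predict(self, features) -> list[Prediction]:
        preds = []
        for f in features:
            f = np.asarray(f, dtype=float)
            X = _standardize(f, self.model.feat_mean, self.model.feat_std)
            p_t = self.model._forward(X[None])[0]
            p_final, label = sequence_label(p_t, self.model.config.fusion)
            preds.append(Prediction(p_t=p_t, p_final=p_final, label=label))
        return preds

    def evaluate(self, features, labels) -> dict:
        """Accuracy / recall / precision / F on a labelled clip set."""
        y = _labels_to_int(labels)
        if len(y) == 0:
            raise ValueError("empty evaluation set")
        preds = self.predict(features)
        yhat = np.array([CLASS_TO_INT[p.label] for p in preds])
        counts = ConfusionCounts(
            tp=int(((yhat == 1) & (y == 1)).sum()),
            fp=int(((yhat == 1) & (y == 0)).sum()),
            fn=int(((yhat == 0) & (y == 1)).sum()),
            tn=int(((yhat == 0) & (y == 0)).sum()),
        )
        out = prf_metrics(counts)
        out["n"] = int(len(y))
        out["p_final"] = [p.p_final for p in preds]
        return out

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Sequence tool classifier (LSTM + per-timestep MLP)",
            "=" * 52,
            f"clips: {len(self.model.features)}   T: {cfg.T}   features: {cfg.feature_dim}-d",
            f"LSTM hidden: {cfg.recurrent_hidden}   head hidden: {cfg.head_hidden}",
            f"dropout: {cfg.dropout}   lr: {cfg.learning_rate}   batch: {cfg.batch_size}",
            f"class weights (neg, pos): ({self.class_weights[0]:.4f}, {self.class_weights[1]:.4f})",
            f"epochs: {len(self.loss_history)}   fusion: {cfg.fusion}   seed: {cfg.seed}",
        ]
        if self.loss_history:
            lines.append(
                f"training loss: {self.loss_history[0]:.4f} (epoch 1) -> "
                f"{self.loss_history[-1]:.4f} (epoch {len(self.loss_history)})"
            )
        return "\n".join(lines)

    def save_sidecar(self, path: str | Path) -> None:
        """JSON sidecar: config, seed, class mapping, loss history."""
        payload = {
            "config": asdict(self.model.config),
            "class_mapping": CLASS_TO_INT,
            "class_weights": list(self.class_weights),
            "loss_history": self.loss_history,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


class PerFrameBaseline(_NetworkMixin):
    """Single-crop classifier: the same MLP head on per-frame features, no LSTM.

    Measures how much tool-class signal individual hand crops carry.  When
    the two classes differ only in motion, this model has nothing to learn
    and stays at chance.
    """

    def __init__(self, frame_features, labels, config: ClassifierConfig | None = None):
        self.config = config or ClassifierConfig()
        self.X = np.asarray(frame_features, dtype=float)
        self.y = _labels_to_int(labels)
        if self.X.ndim != 2 or self.X.shape[1] != self.config.feature_dim:
            raise ValueError(f"expected (N, {self.config.feature_dim}) frame features")
        if len(self.X) != len(self.y):
            raise ValueError("features and labels length mismatch")
        if len(self.X) and len(np.unique(self.y)) < 2:
            raise ValueError("training set must contain both classes")
        self._rng = np.random.default_rng(self.config.seed)
        self.head = nn.MLPHead(self.config.feature_dim, self.config.head_hidden, self._rng)
        self.drop = nn.Dropout(self.config.dropout)
        self.feat_mean = self.X.mean(axis=0)
        self.feat_std = self.X.std(axis=0) + 1e-8

    def _modules(self):
        return [("head", self.head)]

    def _forward(self, X, train=False, rng=None):
        Xd = self.drop.forward(X, rng or self._rng, train)
        return self.head.forward(Xd, train=train)

    def _backward(self, dz):
        head_grads, dX = self.head.backward(dz)
        self.drop.backward(dX)
        return {f"head.{k}": v for k, v in head_grads.items()}

    def fit(self, epochs: int | None = None) -> "PerFrameBaselineResults":
        cfg = self.config
        n_epochs = cfg.epochs if epochs is None else epochs
        weights = cfg.class_weights or (1.0, 1.0)
        optimizer = nn.Adam(lr=cfg.learning_rate)
        n = len(self.X)
        Xs = _standardize(self.X, self.feat_mean, self.feat_std)
        batch = max(cfg.batch_size * cfg.T, 32)  # frames, matching clip volume
        history = []
        for _epoch in range(n_epochs):
            order = self._rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                X = Xs[idx][:, None, :]  # (B, 1, d): a frame is a length-1 clip
                loss, grads = self._loss_and_grads(X, self.y[idx], weights, self._rng)
                self._apply_step(optimizer, grads, cfg.grad_clip)
                epoch_loss += loss
                n_batches += 1
            history.append(epoch_loss / max(n_batches, 1))
        return PerFrameBaselineResults(self, history)


@dataclass
class PerFrameBaselineResults:
    model: PerFrameBaseline
    loss_history: list[float]

    def predict_proba(self, frame_features) -> np.ndarray:
        X = np.asarray(frame_features, dtype=float)
        if X.shape[0] == 0:
            raise ValueError("empty evaluation set")
        Xs = _standardize(X, self.model.feat_mean, self.model.feat_std)
        return self.model._forward(Xs[:, None, :])[:, 0]

    def evaluate(self, frame_features, labels) -> dict:
        y = _labels_to_int(labels)
        if len(y) == 0:
            raise ValueError("empty evaluation set")
        p = self.predict_proba(frame_features)
        yhat = (p >= 0.5).astype(int)
        counts = ConfusionCounts(
            tp=int(((yhat == 1) & (y == 1)).sum()),
            fp=int(((yhat == 1) & (y == 0)).sum()),
            fn=int(((yhat == 0) & (y == 1)).sum()),
            tn=int(((yhat == 0) & (y == 0)).sum()),
        )
        out = prf_metrics(counts)
        out["n"] = int(len(y))
        return out

    def summary(self) -> str:
        return (
            "Per-frame baseline (MLP head on single crops, no recurrence)\n"
            f"frames: {len(self.model.X)}   epochs: {len(self.loss_history)}"
        )
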