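"""Five-layer MLP classifier: architecture, training, and hyperparameter search.

The default multiclass architecture is dense(h1) -> dropout(0.2) ->
dense(h2) -> dropout(0.2) -> dense(n_classes, softmax): five layers with
rectified-linear hidden activations.  The binary variant ends in a single
sigmoid unit trained with binary cross-entropy.

Everything is plain NumPy: seeded uniform fan-in weight initialization
(U(-1/sqrt(fan_in), 1/sqrt(fan_in))), inverted dropout active only during
training, Adam updates, and mini-batch shuffling from one seeded generator —
so training is bit-reproducible from (model seed, training seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from myogrip.features import FeatureVector

__all__ = [
    "MLPModel",
    "TrainingConfig",
    "LabeledDataset",
    "Prediction",
    "TrainingHistory",
    "build_model",
    "forward",
    "forward_batch",
    "train",
    "random_search",
    "save_model",
    "load_model",
]

_ADAM_B1, _ADAM_B2, _ADAM_EPS = 0.9, 0.999, 1e-8


@dataclass
class Prediction:
    """Classifier output for one feature vector."""

    class_id: int
    probabilities: np.ndarray  # per-class, sums to 1 (sigmoid mapped to [1-p, p])
    confidence: float  # max probability

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)


@dataclass
class MLPModel:
    """Layered weights/biases with activations.

    ``layer_spec`` lists the five (or more) layers in order, each a
    ``("dense", width)`` or ``("dropout", rate)`` pair.  ``weights[i]`` has
    shape (fan_in, fan_out) for the i-th dense layer.
    """

    layer_spec: list[tuple[str, float]]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    n_inputs: int
    classes: list[int]
    hidden_activation: str = "relu"
    output_activation: str = "softmax"  # "softmax" | "sigmoid"
    seed: int = 0

    @property
    def n_layers(self) -> int:
        return len(self.layer_spec)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def dropout_rates(self) -> list[float]:
        return [r for kind, r in self.layer_spec if kind == "dropout"]

    def class_index(self, class_id: int) -> int:
        return self.classes.index(class_id)


@dataclass(frozen=True)
class TrainingConfig:
    """Training regime: loss, Adam step size, epochs, batching, and data split."""

    loss: str = "categorical"  # "categorical" | "binary"
    learning_rate: float = 0.001
    epochs: int = 300
    batch_size: int = 8
    dropout_rate: float = 0.20
    splits: tuple[float, float, float] = (0.6, 0.2, 0.2)  # train, val, test
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss not in ("categorical", "binary"):
            raise ValueError("loss must be 'categorical' or 'binary'")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not np.isclose(sum(self.splits), 1.0):
            raise ValueError(f"split fractions must sum to 1, got {self.splits}")


class LabeledDataset:
    """Ordered (feature vector, class label) pairs sharing one layout."""

    def __init__(self, X: np.ndarray, y: np.ndarray, classes: list[int] | None = None):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be (n, d) with one label per row")
        self.classes = sorted(set(self.y.tolist())) if classes is None else list(classes)
        unknown = set(self.y.tolist()) - set(self.classes)
        if unknown:
            raise ValueError(f"labels outside the class set: {sorted(unknown)}")

    @classmethod
    def from_feature_vectors(cls, fvs: list[FeatureVector]) -> "LabeledDataset":
        if any(fv.label is None for fv in fvs):
            raise ValueError("all feature vectors must be labeled")
        X = np.stack([fv.values for fv in fvs])
        y = np.array([fv.label for fv in fvs], dtype=int)
        return cls(X, y)

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(self.X[idx], self.y[idx], classes=self.classes)


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)


def build_model(
    n_inputs: int,
    classes: list[int],
    hidden_widths: tuple[int, int] = (32, 16),
    dropout_rate: float = 0.20,
    binary: bool = False,
    seed: int = 0,
) -> MLPModel:
    """Construct the five-layer network with seeded random initial weights."""
    if n_inputs < 1 or any(w < 1 for w in hidden_widths):
        raise ValueError("layer widths must be positive")
    if not (0.0 < dropout_rate < 1.0):
        raise ValueError("dropout rate must lie in (0, 1)")
    classes = sorted(classes)
    if binary and len(classes) != 2:
        raise ValueError("binary model requires exactly two classes")
    out_width = 1 if binary else len(classes)
    layer_spec: list[tuple[str, float]] = []
    widths = [n_inputs]
    for h in hidden_widths:
        layer_spec.append(("dense", h))
        layer_spec.append(("dropout", dropout_rate))
        widths.append(h)
    layer_spec.append(("dense", out_width))
    widths.append(out_width)

    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        limit = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return MLPModel(
        layer_spec=layer_spec,
        weights=weights,
        biases=biases,
        n_inputs=n_inputs,
        classes=classes,
        output_activation="sigmoid" if binary else "softmax",
        seed=seed,
    )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def forward_batch(
    model: MLPModel,
    X: np.ndarray,
    training: bool = False,
    rng: np.random.Generator | None = None,
    keep_cache: bool = False,
):
    """Batch forward pass; dropout is applied only when ``training`` is true.

    Returns the output probabilities, plus the per-layer cache needed for
    backprop when ``keep_cache`` is set.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_inputs:
        raise ValueError(f"input width {X.shape[1]} != model n_inputs {model.n_inputs}")
    a = X
    cache = {"activations": [X], "pre": [], "masks": []}
    dense_i = 0
    n_dense = len(model.weights)
    for kind, param in model.layer_spec:
        if kind == "dense":
            z = a @ model.weights[dense_i] + model.biases[dense_i]
            cache["pre"].append(z)
            if dense_i == n_dense - 1:
                a = _softmax(z) if model.output_activation == "softmax" else _sigmoid(z)
            else:
                a = np.maximum(z, 0.0)
            cache["activations"].append(a)
            dense_i += 1
        elif kind == "dropout":
            if training:
                if rng is None:
                    raise ValueError("dropout during training requires an rng")
                mask = (rng.random(a.shape) >= param) / (1.0 - param)
            else:
                mask = np.ones_like(a)
            cache["masks"].append(mask)
            a = a * mask
            cache["activations"][-1] = a  # dropout folds into the preceding activation
        else:  # pragma: no cover
            raise ValueError(f"unknown layer kind {kind!r}")
    return (a, cache) if keep_cache else (a, None)


def _probabilities(model: MLPModel, out: np.ndarray) -> np.ndarray:
    """Map raw network output to a per-class probability vector."""
    if model.output_activation == "sigmoid":
        p = float(out[0])
        return np.array([1.0 - p, p])
    return out


def forward(model: MLPModel, fv: FeatureVector | np.ndarray) -> Prediction:
    """Deterministic inference for a single feature vector.

    The predicted class is the argmax of the class probabilities; exact ties
    break toward the lowest class index.
    """
    x = fv.values if isinstance(fv, FeatureVector) else np.asarray(fv, dtype=float)
    out, _ = forward_batch(model, x[None, :], training=False)
    proba = _probabilities(model, out[0])
    idx = int(np.argmax(proba))  # np.argmax returns the first (lowest) index on ties
    return Prediction(
        class_id=model.classes[idx],
        probabilities=proba,
        confidence=float(proba[idx]),
    )


def predict_batch(model: MLPModel, X: np.ndarray) -> np.ndarray:
    out, _ = forward_batch(model, X, training=False)
    if model.output_activation == "sigmoid":
        proba = np.column_stack([1.0 - out[:, 0], out[:, 0]])
    else:
        proba = out
    idx = np.argmax(proba, axis=1)
    return np.array([model.classes[i] for i in idx])


def predict_proba(model: MLPModel, X: np.ndarray) -> np.ndarray:
    out, _ = forward_batch(model, X, training=False)
    if model.output_activation == "sigmoid":
        return np.column_stack([1.0 - out[:, 0], out[:, 0]])
    return out


def _targets(model: MLPModel, y: np.ndarray, loss: str) -> np.ndarray:
    if loss == "binary":
        if model.output_activation != "sigmoid":
            raise ValueError("binary loss requires the sigmoid output variant")
        return (y == model.classes[1]).astype(float)[:, None]
    onehot = np.zeros((y.shape[0], model.n_classes))
    for i, lab in enumerate(y):
        onehot[i, model.class_index(int(lab))] = 1.0
    return onehot


def _loss_value(out: np.ndarray, target: np.ndarray, loss: str) -> float:
    eps = 1e-12
    if loss == "binary":
        p = np.clip(out, eps, 1 - eps)
        return float(-np.mean(target * np.log(p) + (1 - target) * np.log(1 - p)))
    p = np.clip(out, eps, None)
    return float(-np.mean(np.sum(target * np.log(p), axis=1)))


def _accuracy(model: MLPModel, X: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(predict_batch(model, X) == y))


def stratified_split(
    y: np.ndarray, fractions: tuple[float, float, float], seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded per-class split into train/val/test index arrays."""
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for cls in sorted(set(y.tolist())):
        idx = np.where(y == cls)[0]
        rng.shuffle(idx)
        n = len(idx)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        train.extend(idx[:n_train])
        val.extend(idx[n_train : n_train + n_val])
        test.extend(idx[n_train + n_val :])
    return np.array(train, dtype=int), np.array(val, dtype=int), np.array(test, dtype=int)


def train(
    model: MLPModel,
    data: LabeledDataset,
    cfg: TrainingConfig,
    presplit: bool = False,
) -> TrainingHistory:
    """Train the model in place with mini-batch Adam; returns the history.

    By default the dataset is split per ``cfg.splits`` (seeded, stratified)
    and the model is fit on the train fraction with per-epoch validation
    metrics.  With ``presplit=True`` the whole dataset is treated as the
    training split (used inside cross-validation folds).
    """
    if presplit:
        train_set, val_set = data, None
    else:
        tr_idx, va_idx, _ = stratified_split(data.y, cfg.splits, cfg.seed)
        train_set = data.subset(tr_idx)
        val_set = data.subset(va_idx) if len(va_idx) else None
    for cls in model.classes:
        if not np.any(train_set.y == cls):
            raise ValueError(f"class {cls} has no samples in the training split")

    loss_kind = cfg.loss
    if model.output_activation == "sigmoid" and loss_kind == "categorical":
        loss_kind = "binary"  # single sigmoid unit: the two-class special case

    X, y = train_set.X, train_set.y
    T = _targets(model, y, loss_kind)
    rng = np.random.default_rng(cfg.seed)
    m_w = [np.zeros_like(w) for w in model.weights]
    v_w = [np.zeros_like(w) for w in model.weights]
    m_b = [np.zeros_like(b) for b in model.biases]
    v_b = [np.zeros_like(b) for b in model.biases]
    step = 0
    history = TrainingHistory()

    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(X))
        for start in range(0, len(X), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            xb, tb = X[batch], T[batch]
            out, cache = forward_batch(model, xb, training=True, rng=rng, keep_cache=True)
            # softmax+CE and sigmoid+BCE share the same output-layer gradient
            delta = (out - tb) / len(batch)
            grads_w, grads_b = _backprop(model, cache, delta)
            step += 1
            lr_t = cfg.learning_rate * np.sqrt(1 - _ADAM_B2**step) / (1 - _ADAM_B1**step)
            for i in range(len(model.weights)):
                m_w[i] = _ADAM_B1 * m_w[i] + (1 - _ADAM_B1) * grads_w[i]
                v_w[i] = _ADAM_B2 * v_w[i] + (1 - _ADAM_B2) * grads_w[i] ** 2
                model.weights[i] -= lr_t * m_w[i] / (np.sqrt(v_w[i]) + _ADAM_EPS)
                m_b[i] = _ADAM_B1 * m_b[i] + (1 - _ADAM_B1) * grads_b[i]
                v_b[i] = _ADAM_B2 * v_b[i] + (1 - _ADAM_B2) * grads_b[i] ** 2
                model.biases[i] -= lr_t * m_b[i] / (np.sqrt(v_b[i]) + _ADAM_EPS)

        out_full, _ = forward_batch(model, X, training=False)
        ep_loss = _loss_value(out_full, T, loss_kind)
        if not np.isfinite(ep_loss):
            raise FloatingPointError(
                f"training diverged: loss became {ep_loss} at epoch {_epoch + 1} "
                f"(lr={cfg.learning_rate})"
            )
        history.loss.append(ep_loss)
        history.accuracy.append(_accuracy(model, X, y))
        if val_set is not None:
            vout, _ = forward_batch(model, val_set.X, training=False)
            history.val_loss.append(
                _loss_value(vout, _targets(model, val_set.y, loss_kind), loss_kind)
            )
            history.val_accuracy.append(_accuracy(model, val_set.X, val_set.y))
    return history


def _backprop(model: MLPModel, cache: dict, delta: np.ndarray):
    """Gradients for all dense layers given the output-layer delta."""
    grads_w = [None] * len(model.weights)
    grads_b = [None] * len(model.weights)
    dense_positions = [i for i, (k, _) in enumerate(model.layer_spec) if k == "dense"]
    masks = cache["masks"]
    n_dense = len(model.weights)
    # activations[j] is the input to the j-th dense layer (dropout already folded in)
    for j in range(n_dense - 1, -1, -1):
        a_in = cache["activations"][j]
        grads_w[j] = a_in.T @ delta
        grads_b[j] = delta.sum(axis=0)
        if j > 0:
            delta = delta @ model.weights[j].T
            delta = delta * masks[j - 1]  # dropout mask between dense j-1 and j
            delta = delta * (cache["pre"][j - 1] > 0)  # relu derivative
    return grads_w, grads_b


def random_search(
    data: LabeledDataset,
    n_draws: int,
    lr_range: tuple[float, float] = (1e-4, 1e-2),
    epoch_grid: tuple[int, ...] = (100, 200, 300),
    base_cfg: TrainingConfig | None = None,
    hidden_widths: tuple[int, int] = (32, 16),
    seed: int = 0,
):
    """Random hyperparameter search over learning rate and epoch count.

    Each draw samples the learning rate log-uniformly from ``lr_range`` and
    epochs uniformly from ``epoch_grid`` (batch size held constant), trains a
    fresh model on the train split, and scores validation accuracy.  Returns
    ``(best_cfg, trials)`` where ``trials`` is a list of per-draw records;
    ties break toward the first-seen draw.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    base_cfg = base_cfg or TrainingConfig(seed=seed)
    rng = np.random.default_rng(seed)
    trials = []
    best_cfg, best_acc = None, -np.inf
    for draw in range(n_draws):
        lr = float(np.exp(rng.uniform(np.log(lr_range[0]), np.log(lr_range[1]))))
        epochs = int(rng.choice(epoch_grid))
        cfg = replace(base_cfg, learning_rate=lr, epochs=epochs, seed=seed)
        record = {"draw": draw, "learning_rate": lr, "epochs": epochs}
        try:
            model = build_model(
                data.X.shape[1],
                data.classes,
                hidden_widths=hidden_widths,
                dropout_rate=cfg.dropout_rate,
                binary=False,
                seed=seed + draw,
            )
            history = train(model, data, cfg)
            acc = history.val_accuracy[-1] if history.val_accuracy else history.accuracy[-1]
            record.update(val_accuracy=acc, error=None)
            if acc > best_acc:
                best_acc, best_cfg = acc, cfg
        except Exception as exc:
            record.update(val_accuracy=np.nan, error=str(exc))
        trials.append(record)
    if best_cfg is None:
        raise RuntimeError("all random-search trials failed")
    return best_cfg, trials


def save_model(model: MLPModel, path: str | Path) -> Path:
    """Serialize architecture plus flat weight arrays to portable JSON."""
    path = Path(path)
    payload = {
        "format": "myogrip-mlp-v1",
        "layer_spec": [[k, p] for k, p in model.layer_spec],
        "n_inputs": model.n_inputs,
        "classes": model.classes,
        "hidden_activation": model.hidden_activation,
        "output_activation": model.output_activation,
        "seed": model.seed,
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
    }
    path.write_text(json.dumps(payload))
    return path


def load_model(path: str | Path) -> MLPModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "myogrip-mlp-v1":
        raise ValueError(f"{path}: not a recognized model file")
    return MLPModel(
        layer_spec=[(k, p) for k, p in payload["layer_spec"]],
        weights=[np.array(w, dtype=float) for w in payload["weights"]],
        biases=[np.array(b, dtype=float) for b in payload["biases"]],
        n_inputs=int(payload["n_inputs"]),
        classes=[int(c) for c in payload["classes"]],
        hidden_activation=payload["hidden_activation"],
        output_activation=payload["output_activation"],
        seed=int(payload["seed"]),
    )
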