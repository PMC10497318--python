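"""From-scratch backpropagation neural network for 5-class gesture decoding.

Fixed topology: ``n_in`` inputs (4..20 feature columns), two hidden layers
of 20 and 8 neurons (tanh by default, sigmoid available), and a 5-way
softmax output trained with cross-entropy loss by plain mini-batch
stochastic gradient descent without momentum.  Inputs
are z-scored with statistics fitted on the training rows only and stored on
the model, so held-out and cross-electrode data are normalized consistently.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from .errors import ConfigurationError, FeatureMismatchError
from .features import FeatureDataset
from .protocol import CLASS_ORDER

HIDDEN_SIZES = (20, 8)
N_CLASSES = 5


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    batch_size: int = 256
    max_epochs: int = 542
    validation_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.max_epochs < 1:
            raise ConfigurationError("max_epochs must be >= 1")
        if not 0 <= self.validation_fraction < 1:
            raise ConfigurationError("validation_fraction must be in [0, 1)")


@dataclass
class NetworkModel:
    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    hidden_activation: str = "sigmoid"
    rng_seed: int = 0
    class_labels: tuple[str, ...] = CLASS_ORDER
    # set by train(); None until then
    feature_names: tuple[str, ...] | None = None
    channels: tuple[int, ...] | None = None
    norm_mean: np.ndarray | None = None
    norm_scale: np.ndarray | None = None
    train_electrode: str = ""

    @property
    def n_in(self) -> int:
        return self.layer_sizes[0]


def init_network(
    n_in: int,
    seed: int = 0,
    hidden: tuple[int, int] = HIDDEN_SIZES,
    n_out: int = N_CLASSES,
    hidden_activation: str = "tanh",
) -> NetworkModel:
    """Reproducible small-magnitude random initialization.

    Weights are drawn N(0, 1/fan_in) to break symmetry while keeping the
    sigmoid pre-activations in their sensitive range; biases start at zero.
    """
    if not 4 <= n_in <= 20:
        raise ConfigurationError(f"n_in must be within [4, 20], got {n_in}")
    sizes = (n_in, *hidden, n_out)
    rng = np.random.default_rng(seed)
    weights = [
        rng.normal(0.0, 1.0 / np.sqrt(sizes[i]), size=(sizes[i], sizes[i + 1]))
        for i in range(len(sizes) - 1)
    ]
    biases = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
    if hidden_activation not in _ACTIVATIONS:
        raise ConfigurationError(
            f"unknown hidden activation {hidden_activation!r}; "
            f"known: {sorted(_ACTIVATIONS)}"
        )
    return NetworkModel(
        layer_sizes=sizes,
        weights=weights,
        biases=biases,
        rng_seed=seed,
        hidden_activation=hidden_activation,
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


_ACTIVATIONS = {"sigmoid": _sigmoid, "tanh": np.tanh}

# derivative expressed through the activation value a = f(z)
_ACTIVATION_DERIVS = {
    "sigmoid": lambda a: a * (1.0 - a),
    "tanh": lambda a: 1.0 - a**2,
}


def _forward_pass(model: NetworkModel, X: np.ndarray) -> list[np.ndarray]:
    """Activations of every layer, input first, softmax probabilities last."""
    try:
        act = _ACTIVATIONS[model.hidden_activation]
    except KeyError:
        raise ConfigurationError(
            f"unknown hidden activation {model.hidden_activation!r}; "
            f"known: {sorted(_ACTIVATIONS)}"
        ) from None
    acts = [X]
    a = X
    n_layers = len(model.weights)
    for i, (W, b) in enumerate(zip(model.weights, model.biases)):
        z = a @ W + b
        a = _softmax(z) if i == n_layers - 1 else act(z)
        acts.append(a)
    return acts


def forward(model: NetworkModel, X: np.ndarray) -> np.ndarray:
    """Class probability vector(s) for already-normalized feature row(s)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_in:
        raise FeatureMismatchError(
            f"model expects {model.n_in} inputs, got {X.shape[1]}"
        )
    return _forward_pass(model, X)[-1]


def cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    p = np.clip(probs, 1e-12, 1.0)
    return float(-np.mean(np.sum(onehot * np.log(p), axis=1)))


def loss_and_gradients(
    model: NetworkModel, X: np.ndarray, onehot: np.ndarray
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """Mean cross-entropy and its exact gradients by backpropagation."""
    acts = _forward_pass(model, X)
    probs = acts[-1]
    n = X.shape[0]
    loss = cross_entropy(probs, onehot)
    grads_w: list[np.ndarray] = [None] * len(model.weights)  # type: ignore
    grads_b: list[np.ndarray] = [None] * len(model.biases)  # type: ignore
    deriv = _ACTIVATION_DERIVS[model.hidden_activation]
    # softmax + cross-entropy: delta at the output is (p - y) / n
    delta = (probs - onehot) / n
    for i in range(len(model.weights) - 1, -1, -1):
        grads_w[i] = acts[i].T @ delta
        grads_b[i] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ model.weights[i].T) * deriv(acts[i])
    return loss, grads_w, grads_b


def _labels_to_indices(labels: np.ndarray, class_labels: tuple[str, ...]) -> np.ndarray:
    index = {c: i for i, c in enumerate(class_labels)}
    unknown = sorted(set(labels) - set(class_labels))
    if unknown:
        raise FeatureMismatchError(
            f"labels {unknown} are not among model classes {class_labels}"
        )
    return np.array([index[lab] for lab in labels], dtype=int)


def _onehot(idx: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((idx.size, n_classes))
    out[np.arange(idx.size), idx] = 1.0
    return out


def _normalize(model: NetworkModel, X: np.ndarray) -> np.ndarray:
    if model.norm_mean is None or model.norm_scale is None:
        raise ConfigurationError("model has no stored normalization; train it first")
    return (X - model.norm_mean) / model.norm_scale


def train(
    model: NetworkModel, dataset: FeatureDataset, config: TrainConfig
) -> tuple[NetworkModel, dict]:
    """Mini-batch SGD with best-validation checkpointing.

    A stratified ``validation_fraction`` of the rows is held out; after each
    epoch, training and validation loss/accuracy are recorded, and the
    parameters of the epoch with the highest validation accuracy (earliest on
    ties) are restored at the end.  The epoch budget ``max_epochs`` plays the
    role of the stopping epoch.  Deterministic given ``config.seed``.
    """
    X = dataset.matrix
    y_labels = dataset.labels
    if X.shape[0] == 0:
        raise ValueError("empty dataset")
    if X.shape[1] != model.n_in:
        raise FeatureMismatchError(
            f"model expects {model.n_in} feature columns, dataset has {X.shape[1]}"
        )
    y = _labels_to_indices(y_labels, model.class_labels)
    if len(np.unique(y)) == 1:
        warnings.warn("training on a single-class dataset", stacklevel=2)

    idx = np.arange(X.shape[0])
    if config.validation_fraction > 0 and X.shape[0] >= 10:
        strat = y if np.min(np.bincount(y, minlength=1)[np.unique(y)]) >= 2 else None
        train_idx, val_idx = train_test_split(
            idx,
            test_size=config.validation_fraction,
            random_state=config.seed,
            stratify=strat,
        )
    else:
        train_idx, val_idx = idx, np.array([], dtype=int)

    # normalization fitted on the training rows only
    mu = X[train_idx].mean(axis=0)
    sigma = X[train_idx].std(axis=0)
    sigma[sigma == 0] = 1.0
    model.norm_mean = mu
    model.norm_scale = sigma
    model.feature_names = dataset.feature_names
    model.channels = dataset.channels

    Xtr = (X[train_idx] - mu) / sigma
    ytr = y[train_idx]
    Ytr = _onehot(ytr, len(model.class_labels))
    Xval = (X[val_idx] - mu) / sigma if val_idx.size else None
    yval = y[val_idx] if val_idx.size else None

    rng = np.random.default_rng(config.seed)
    history: dict = {
        "train_loss": [],
        "train_accuracy": [],
        "val_loss": [],
        "val_accuracy": [],
    }
    best = {"val_accuracy": -1.0, "epoch": -1, "weights": None, "biases": None}

    n = Xtr.shape[0]
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            _, gw, gb = loss_and_gradients(model, Xtr[batch], Ytr[batch])
            for i in range(len(model.weights)):
                model.weights[i] -= config.learning_rate * gw[i]
                model.biases[i] -= config.learning_rate * gb[i]

        probs_tr = _forward_pass(model, Xtr)[-1]
        history["train_loss"].append(cross_entropy(probs_tr, Ytr))
        history["train_accuracy"].append(
            float(np.mean(probs_tr.argmax(axis=1) == ytr))
        )
        if Xval is not None:
            probs_val = _forward_pass(model, Xval)[-1]
            val_acc = float(np.mean(probs_val.argmax(axis=1) == yval))
            history["val_loss"].append(
                cross_entropy(probs_val, _onehot(yval, len(model.class_labels)))
            )
            history["val_accuracy"].append(val_acc)
        else:
            val_acc = history["train_accuracy"][-1]
            history["val_loss"].append(history["train_loss"][-1])
            history["val_accuracy"].append(val_acc)
        if val_acc > best["val_accuracy"]:
            best.update(
                val_accuracy=val_acc,
                epoch=epoch,
                weights=[w.copy() for w in model.weights],
                biases=[b.copy() for b in model.biases],
            )

    if best["weights"] is not None:
        model.weights = best["weights"]
        model.biases = best["biases"]
    history["best_epoch"] = best["epoch"]
    history["best_val_accuracy"] = best["val_accuracy"]
    history["final_train_accuracy"] = history["train_accuracy"][best["epoch"]]
    return model, history


@dataclass
class EvaluationReport:
    """Confusion matrix and derived rates for one model/dataset pairing."""

    confusion: np.ndarray  # (n_classes, n_classes), rows = true
    accuracy: float
    per_class_recall: np.ndarray
    class_labels: tuple[str, ...]
    provenance: tuple[str, str]  # (train_electrode, test_electrode)
    n: int

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "per_class_recall": self.per_class_recall.tolist(),
            "class_labels": list(self.class_labels),
            "provenance": list(self.provenance),
            "n": self.n,
        }


def evaluate(
    model: NetworkModel,
    dataset: FeatureDataset,
    provenance: tuple[str, str] | None = None,
) -> EvaluationReport:
    """Argmax decision rule on normalized features; ties resolve to the
    lowest class index."""
    from sklearn.metrics import confusion_matrix

    X = dataset.matrix
    if X.shape[0] == 0:
        raise ValueError("empty test set")
    if model.feature_names is not None and (
        tuple(dataset.feature_names) != tuple(model.feature_names)
        or tuple(dataset.channels) != tuple(model.channels)
    ):
        raise FeatureMismatchError(
            f"model was trained on {model.feature_names} x ch{model.channels}, "
            f"dataset provides {dataset.feature_names} x ch{dataset.channels}"
        )
    if X.shape[1] != model.n_in:
        raise FeatureMismatchError(
            f"model expects {model.n_in} feature columns, dataset has {X.shape[1]}"
        )
    y = _labels_to_indices(dataset.labels, model.class_labels)
    probs = _forward_pass(model, _normalize(model, X))[-1]
    pred = probs.argmax(axis=1)
    k = len(model.class_labels)
    conf = confusion_matrix(y, pred, labels=list(range(k)))
    row_sums = conf.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(row_sums > 0, np.diag(conf) / row_sums, 0.0)
    if provenance is None:
        provenance = (model.train_electrode, str(dataset.df["electrode"].iloc[0])
                      if "electrode" in dataset.df.columns else "")
    return EvaluationReport(
        confusion=conf,
        accuracy=float(np.trace(conf) / conf.sum()),
        per_class_recall=recall,
        class_labels=model.class_labels,
        provenance=provenance,
        n=int(conf.sum()),
    )


def cross_evaluate(
    model: NetworkModel,
    dataset: FeatureDataset,
    norm_source: str = "model",
    provenance: tuple[str, str] | None = None,
) -> EvaluationReport:
    """Evaluate a model on data from a different electrode arm.

    The dataset is restricted/reordered to the model's feature subset.
    ``norm_source`` selects the z-score statistics: ``"model"`` (stored
    training statistics, default) or ``"data"`` (refitted on the given rows).
    """
    if model.feature_names is None:
        raise ConfigurationError("model has not been trained")
    try:
        sub = dataset.select(model.feature_names, model.channels)
    except KeyError as exc:
        raise FeatureMismatchError(
            f"dataset cannot supply the model's feature subset: {exc}"
        ) from exc
    if norm_source == "model":
        return evaluate(model, sub, provenance=provenance)
    if norm_source != "data":
        raise ConfigurationError(f"unknown norm_source {norm_source!r}")
    saved = (model.norm_mean, model.norm_scale)
    X = sub.matrix
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)
    sigma[sigma == 0] = 1.0
    try:
        model.norm_mean, model.norm_scale = mu, sigma
        return evaluate(model, sub, provenance=provenance)
    finally:
        model.norm_mean, model.norm_scale = saved


# -- persistence --------------------------------------------------------------

def save_model(model: NetworkModel, path) -> Path:
    path = Path(path)
    payload = {
        "layer_sizes": list(model.layer_sizes),
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "hidden_activation": model.hidden_activation,
        "rng_seed": model.rng_seed,
        "class_labels": list(model.class_labels),
        "feature_names": list(model.feature_names) if model.feature_names else None,
        "channels": list(model.channels) if model.channels else None,
        "norm_mean": model.norm_mean.tolist() if model.norm_mean is not None else None,
        "norm_scale": model.norm_scale.tolist()
        if model.norm_scale is not None
        else None,
        "train_electrode": model.train_electrode,
    }
    path.write_text(json.dumps(payload))
    return path


def load_model(path) -> NetworkModel:
    payload = json.loads(Path(path).read_text())
    return NetworkModel(
        layer_sizes=tuple(payload["layer_sizes"]),
        weights=[np.array(w) for w in payload["weights"]],
        biases=[np.array(b) for b in payload["biases"]],
        hidden_activation=payload["hidden_activation"],
        rng_seed=payload["rng_seed"],
        class_labels=tuple(payload["class_labels"]),
        feature_names=tuple(payload["feature_names"])
        if payload["feature_names"]
        else None,
        channels=tuple(payload["channels"]) if payload["channels"] else None,
        norm_mean=np.array(payload["norm_mean"])
        if payload["norm_mean"] is not None
        else None,
        norm_scale=np.array(payload["norm_scale"])
        if payload["norm_scale"] is not None
        else None,
        train_electrode=payload.get("train_electrode", ""),
    )
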