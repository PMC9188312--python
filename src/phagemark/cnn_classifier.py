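"""The convolutional sequence classifier.

Architecture: a 1-D convolution along the sequence (length-``kernel_len``
window spanning all 20 one-hot channels, ``n_filters`` output channels,
ReLU), global max-pooling over positions, dropout, a dense ReLU layer of
``n_dense`` units, dropout, and a softmax output over the K categories.
The convolution filters act as learned motif detectors; global max-pooling
records each motif's best match anywhere in the sequence, which is what
makes the features position-invariant.

Training minimises mean categorical cross-entropy (natural log) with Adam.
All randomness (init, shuffling, dropout) derives from the config seed, so
a given seed reproduces the training history exactly.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from phagemark import nn
from phagemark.encoding import DEFAULT_ALPHABET, DEFAULT_LEN_W

MODEL_FORMAT_VERSION = 1


@dataclass
class ModelConfig:
    """Hyperparameters of the CNN.

    Defaults follow the tuned configuration: window 900, kernel length 7,
    50 filters, 100 dense units, dropout 0.1.  Optimiser settings (Adam,
    lr 1e-3, batch 64, 20 epochs) are conventional defaults.
    """

    len_w: int = DEFAULT_LEN_W
    n_classes: int = 4
    kernel_len: int = 7
    n_filters: int = 50
    n_dense: int = 100
    dropout_rate: float = 0.1
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if not (0.0 <= self.dropout_rate < 1.0):
            problems.append(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.kernel_len > self.len_w:
            problems.append(f"kernel_len ({self.kernel_len}) exceeds len_w ({self.len_w})")
        if self.n_classes < 2:
            problems.append(f"n_classes must be >= 2, got {self.n_classes}")
        if min(self.len_w, self.kernel_len, self.n_filters, self.n_dense,
               self.batch_size, self.epochs) < 1:
            problems.append("len_w, kernel_len, n_filters, n_dense, batch_size, epochs must be >= 1")
        if self.learning_rate <= 0:
            problems.append(f"learning_rate must be positive, got {self.learning_rate}")
        if problems:
            raise ValueError("invalid ModelConfig: " + "; ".join(problems))


@dataclass
class TrainedModel:
    """Model parameters plus everything needed to reapply them.

    ``category_order`` maps output indices to category names ("others"
    last); ``alphabet`` records the one-hot column order the model was
    trained with, so encodings stay consistent across save/load.
    """

    config: ModelConfig
    category_order: list[str]
    alphabet: str = DEFAULT_ALPHABET
    params: dict[str, np.ndarray] = field(default_factory=dict)
    history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.category_order) != self.config.n_classes:
            raise ValueError(
                f"category_order has {len(self.category_order)} names "
                f"but n_classes is {self.config.n_classes}"
            )

    def parameter_counts(self) -> dict[str, int]:
        """Actual parameter count per layer (conv, first dense, output)."""
        return {
            "conv": self.params["W_conv"].size + self.params["b_conv"].size,
            "dense": self.params["W_dense"].size + self.params["b_dense"].size,
            "output": self.params["W_out"].size + self.params["b_out"].size,
        }


def build_model(
    config: ModelConfig,
    category_order: list[str] | None = None,
    alphabet: str = DEFAULT_ALPHABET,
) -> TrainedModel:
    """Initialise an untrained model with seeded random weights."""
    if category_order is None:
        category_order = [f"class_{i}" for i in range(config.n_classes - 1)] + ["others"]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0]))
    params = nn.init_params(
        config.kernel_len, config.n_filters, config.n_dense, config.n_classes, rng
    )
    return TrainedModel(config=config, category_order=category_order,
                        alphabet=alphabet, params=params)


def _epoch_eval(model: TrainedModel, X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    probs = predict_proba(model, X)
    loss = nn.cross_entropy(probs, y)
    acc = float((probs.argmax(axis=1) == y).mean())
    return loss, acc


def train(
    model: TrainedModel,
    X: np.ndarray,
    y: np.ndarray | list[int],
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> TrainedModel:
    """Train in place by minibatch Adam on mean cross-entropy.

    ``y`` holds integer labels indexed against ``model.category_order``.
    Every class must appear at least once.  The per-epoch history records
    train (and, if given, validation) loss and accuracy.
    """
    cfg = model.config
    y = np.asarray(y, dtype=np.int64)
    X = np.asarray(X, dtype=np.float32)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y differ in length")
    if X.shape[1] != cfg.len_w:
        raise ValueError(f"expected len_w={cfg.len_w}, got input length {X.shape[1]}")
    present = set(np.unique(y).tolist())
    missing = [model.category_order[k] for k in range(cfg.n_classes) if k not in present]
    if missing:
        raise ValueError(f"classes absent from training data: {missing}")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7E]))
    opt = nn.Adam(model.params, lr=cfg.learning_rate)
    for epoch in range(cfg.epochs):
        batch_losses, batch_sizes = [], []
        for idx in nn.minibatches(len(y), cfg.batch_size, rng):
            probs, cache = nn.forward(
                model.params, X[idx], cfg.kernel_len,
                dropout_rate=cfg.dropout_rate, rng=rng, want_cache=True,
            )
            loss = nn.cross_entropy(probs, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss!r}; "
                    "try a lower learning rate"
                )
            grads = nn.backward(model.params, cache, y[idx])
            opt.step(model.params, grads)
            batch_losses.append(loss)
            batch_sizes.append(len(idx))
        row = {
            "epoch": epoch,
            "train_loss": float(np.average(batch_losses, weights=batch_sizes)),
        }
        _, row["train_acc"] = _epoch_eval(model, X, y)
        if X_val is not None and y_val is not None:
            row["val_loss"], row["val_acc"] = _epoch_eval(
                model, X_val, np.asarray(y_val, dtype=np.int64)
            )
        model.history.append(row)
    return model


def predict_proba(model: TrainedModel, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Softmax probabilities, one row per sequence; dropout disabled."""
    X = np.asarray(X, dtype=np.float32)
    if X.ndim != 3 or X.shape[1] != model.config.len_w or X.shape[2] != 20:
        raise ValueError(
            f"expected batch of shape (n, {model.config.len_w}, 20), got {X.shape}"
        )
    out = np.empty((X.shape[0], model.config.n_classes), dtype=np.float64)
    for start in range(0, X.shape[0], batch_size):
        out[start : start + batch_size] = nn.forward(
            model.params, X[start : start + batch_size], model.config.kernel_len
        )
    return out


def predict_class(p: np.ndarray, category_order: list[str]) -> str:
    """Argmax category; ties break to the lowest index in category_order."""
    p = np.asarray(p)
    if p.ndim != 1 or len(p) != len(category_order):
        raise ValueError("probability vector does not match category_order")
    return category_order[int(p.argmax())]


def crossvalidate(
    config: ModelConfig,
    X: np.ndarray,
    labels: list[str],
    category_order: list[str],
    k: int = 5,
    seed: int = 0,
):
    """Stratified k-fold cross-validation; returns (per-fold reports, mean).

    Each fold trains a fresh model on the remaining folds and evaluates on
    the held-out fold.  Fold assignment is seeded and reproducible.
    """
    from phagemark.evaluation import evaluate, mean_reports

    if k < 2:
        raise ValueError("crossvalidate requires k >= 2 (no held-out fold otherwise)")
    labels = list(labels)
    counts = {c: labels.count(c) for c in category_order}
    small = [c for c, n in counts.items() if n < k]
    if small:
        raise ValueError(f"classes with fewer than k={k} members: {small}")
    idx_of = {c: i for i, c in enumerate(category_order)}
    y = np.array([idx_of[lab] for lab in labels], dtype=np.int64)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        m = build_model(config, category_order)
        train(m, X[tr], y[tr])
        pred = predict_proba(m, X[te]).argmax(axis=1)
        rep = evaluate(
            [category_order[i] for i in y[te]],
            [category_order[i] for i in pred],
            category_order,
        )
        rep.fold = fold
        reports.append(rep)
    return reports, mean_reports(reports)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write a single archive: JSON metadata block + raw weight arrays."""
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "config": asdict(model.config),
        "category_order": model.category_order,
        "alphabet": model.alphabet,
        "history": model.history,
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("metadata.json", json.dumps(meta, indent=1))
        buf = io.BytesIO()
        np.savez(buf, **model.params)
        zf.writestr("weights.npz", buf.getvalue())


def load_model(path: str | Path, expected_alphabet: str | None = None) -> TrainedModel:
    """Inverse of :func:`save_model`; predictions round-trip bit-for-bit.

    Raises on a format-version mismatch, or when ``expected_alphabet`` is
    given and differs from the stored one (the one-hot column order would
    silently scramble inputs otherwise).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no model file at {path}")
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("metadata.json"))
        if meta.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {meta.get('format_version')!r}"
            )
        if expected_alphabet is not None and meta["alphabet"] != expected_alphabet:
            raise ValueError(
                f"model alphabet {meta['alphabet']!r} does not match "
                f"expected {expected_alphabet!r}"
            )
        with np.load(io.BytesIO(zf.read("weights.npz"))) as npz:
            params = {k: npz[k] for k in npz.files}
    return TrainedModel(
        config=ModelConfig(**meta["config"]),
        category_order=meta["category_order"],
        alphabet=meta["alphabet"],
        params=params,
        history=meta["history"],
    )
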