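"""Convolutional classifier of precursor substrate fitness.

The classifier maps a peptide insert (6–12 residues by default), embedded in
its fixed core-template context, to the probability that the full enzymatic
pathway matures the precursor into a thiopeptide (label 1) rather than
leaving a linear or shunt product (label 0).

Inserts of different lengths are center-padded between the fixed flanks:
both insert boundaries abut enzymatic modification sites, so center padding
keeps both boundaries at fixed coordinates across lengths.

The default architecture is a 12-layer 1-D CNN totalling ≈1.2 × 10^7
trainable parameters; a much smaller configuration (:func:`reduced_config`)
is provided for desk-scale training runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin

from .codons import AA_ALPHABET, DEFAULT_TEMPLATE, PrecursorTemplate
from .nn import ConvNet

__all__ = [
    "ModelConfig",
    "reduced_config",
    "encode_peptide",
    "decode_encoding",
    "FitnessCNN",
    "build_classifier",
    "train",
    "evaluate",
    "predict_fitness",
    "save_model",
    "load_model",
]

PAD_INDEX = 20  #: channel index of the padding token
N_CHANNELS = 21  #: 20 residues + pad
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimizer settings of the fitness classifier.

    The default configuration has 12 convolutional layers and ≈1.19 × 10^7
    trainable parameters.
    """

    n_conv_layers: int = 12
    channels: int = 600
    kernel_size: int = 3
    dropout: float = 0.0
    learning_rate: float = 1e-3
    batch_size: int = 256
    epochs: int = 6
    max_len: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conv_layers < 1:
            raise ValueError("layer count must be >= 1")
        if self.channels < 1:
            raise ValueError("channel width must be positive")


def reduced_config(seed: int = 0, **overrides) -> ModelConfig:
    """Desk-scale configuration: 3 conv layers × 48 channels."""
    base = dict(n_conv_layers=3, channels=48, kernel_size=3,
                learning_rate=1e-3, batch_size=256, epochs=6, seed=seed)
    base.update(overrides)
    return ModelConfig(**base)


def encode_peptide(
    insert: str,
    max_len: int = 12,
    template: PrecursorTemplate = DEFAULT_TEMPLATE,
) -> np.ndarray:
    """One-hot encode an insert inside its fixed core flanks.

    Returns a ``(width, 21)`` float32 matrix where
    ``width = len(core_pre) + max_len + len(core_post)``.  The insert is
    center-padded to ``max_len`` (left pad gets the smaller half when the
    deficit is odd); pad columns are one-hot on the pad channel.
    """
    if len(insert) > max_len:
        raise ValueError(f"insert length {len(insert)} exceeds max_len={max_len}")
    deficit = max_len - len(insert)
    lpad = deficit // 2
    rpad = deficit - lpad
    width = len(template.core_pre) + max_len + len(template.core_post)
    m = np.zeros((width, N_CHANNELS), dtype=np.float32)
    col = 0
    for res in template.core_pre:
        m[col, _AA_INDEX[res]] = 1.0
        col += 1
    for _ in range(lpad):
        m[col, PAD_INDEX] = 1.0
        col += 1
    for res in insert:
        if res not in _AA_INDEX:
            raise ValueError(f"unknown residue {res!r} in insert")
        m[col, _AA_INDEX[res]] = 1.0
        col += 1
    for _ in range(rpad):
        m[col, PAD_INDEX] = 1.0
        col += 1
    for res in template.core_post:
        m[col, _AA_INDEX[res]] = 1.0
        col += 1
    return m


def decode_encoding(
    matrix: np.ndarray,
    template: PrecursorTemplate = DEFAULT_TEMPLATE,
) -> str:
    """Invert :func:`encode_peptide`: strip flanks and pad columns."""
    start = len(template.core_pre)
    stop = matrix.shape[0] - len(template.core_post)
    residues = []
    for col in range(start, stop):
        idx = int(matrix[col].argmax())
        if idx != PAD_INDEX:
            residues.append(AA_ALPHABET[idx])
    return "".join(residues)


def _encode_batch(inserts: Sequence[str], max_len: int,
                  template: PrecursorTemplate) -> np.ndarray:
    width = len(template.core_pre) + max_len + len(template.core_post)
    out = np.empty((len(inserts), width, N_CHANNELS), dtype=np.float32)
    for i, s in enumerate(inserts):
        out[i] = encode_peptide(s, max_len, template)
    return out


class FitnessCNN(BaseEstimator, ClassifierMixin):
    """Convolutional classifier of enzymatic substrate fitness.

    scikit-learn style estimator: ``fit(X, y)`` takes a sequence of insert
    strings and binary labels (1 = matured to thiopeptide, 0 = linear/shunt
    product); ``predict_proba`` / ``predict_fitness`` return maturation
    probabilities in [0, 1].

    Parameters mirror :class:`ModelConfig`; ``FitnessCNN(**asdict(config))``
    and :func:`build_classifier` construct matching estimators.
    """

    def __init__(self, n_conv_layers: int = 12, channels: int = 600,
                 kernel_size: int = 3, dropout: float = 0.0,
                 learning_rate: float = 1e-3, batch_size: int = 256,
                 epochs: int = 6, max_len: int = 12, seed: int = 0,
                 validation_fraction: float = 0.1,
                 template: PrecursorTemplate = DEFAULT_TEMPLATE):
        self.n_conv_layers = n_conv_layers
        self.channels = channels
        self.kernel_size = kernel_size
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.max_len = max_len
        self.seed = seed
        self.validation_fraction = validation_fraction
        self.template = template

    # -- construction -----------------------------------------------------
    @property
    def input_width_(self) -> int:
        return (len(self.template.core_pre) + self.max_len
                + len(self.template.core_post))

    def build(self) -> "FitnessCNN":
        """Initialize the (untrained) network so it can predict and report
        its parameter count without fitting."""
        self.net_ = ConvNet(
            in_width=self.input_width_,
            in_channels=N_CHANNELS,
            n_conv_layers=self.n_conv_layers,
            channels=self.channels,
            kernel_size=self.kernel_size,
            dropout=self.dropout,
            seed=self.seed,
        )
        self.n_parameters_ = self.net_.n_parameters()
        self.classes_ = np.array([0, 1])
        return self

    # -- training ---------------------------------------------------------
    def fit(self, X: Sequence[str], y,
            validation_data: tuple[Sequence[str], Sequence[int]] | None = None
            ) -> "FitnessCNN":
        y = np.asarray(y, dtype=np.float32)
        X = list(X)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if len(np.unique(y)) < 2:
            raise ValueError("training data contains a single class; "
                             "need both matured (1) and unmatured (0) examples")
        self.build()
        rng = np.random.default_rng(self.seed)

        if validation_data is None and self.validation_fraction > 0:
            n_val = max(1, int(len(X) * self.validation_fraction))
            perm = rng.permutation(len(X))
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            X_val = [X[i] for i in val_idx]
            y_val = y[val_idx]
            X_tr = [X[i] for i in tr_idx]
            y_tr = y[tr_idx]
        else:
            X_tr, y_tr = X, y
            X_val, y_val = (list(validation_data[0]),
                            np.asarray(validation_data[1], dtype=np.float32)) \
                if validation_data is not None else ([], np.empty(0))

        enc = _encode_batch(X_tr, self.max_len, self.template)
        enc_val = (_encode_batch(X_val, self.max_len, self.template)
                   if len(X_val) else None)

        history: list[dict] = []
        n = enc.shape[0]
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for s in range(0, n, self.batch_size):
                idx = order[s:s + self.batch_size]
                loss, grads = self.net_.loss_and_grads(enc[idx], y_tr[idx], rng)
                self.net_.adam_step(grads, self.learning_rate)
                losses.append(loss)
            row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            if enc_val is not None:
                p = expit(self.net_.predict_logits(enc_val))
                row["val_accuracy"] = float(np.mean((p > 0.5) == (y_val > 0.5)))
            history.append(row)
        self.history_ = history
        return self

    # -- inference --------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise RuntimeError("model is not built; call fit() or build()")

    def predict_fitness(self, inserts: Sequence[str]) -> np.ndarray:
        """Maturation probabilities, batch order preserved."""
        self._check_fitted()
        inserts = list(inserts)
        if not inserts:
            return np.empty(0)
        for s in inserts:
            if len(s) > self.max_len or len(s) < 1:
                raise ValueError(
                    f"insert length {len(s)} unsupported; the encoder supports "
                    f"lengths 1..{self.max_len}")
        # deduplicate so identical inserts map to bit-identical probabilities
        unique = sorted(set(inserts))
        enc = _encode_batch(unique, self.max_len, self.template)
        logits = self.net_.predict_logits(enc).astype(np.float64)
        lookup = dict(zip(unique, expit(logits)))
        return np.array([lookup[s] for s in inserts])

    def predict_proba(self, X: Sequence[str]) -> np.ndarray:
        p1 = self.predict_fitness(X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: Sequence[str]) -> np.ndarray:
        # threshold 0.5, ties resolved toward label 0
        return (self.predict_fitness(X) > 0.5).astype(int)


def build_classifier(config: ModelConfig | None = None) -> FitnessCNN:
    """Instantiate an untrained classifier from a config and build its
    network so the parameter count is available immediately."""
    config = config or ModelConfig()
    est = FitnessCNN(**asdict(config))
    return est.build()


def train(model: FitnessCNN, dataset, config: ModelConfig | None = None):
    """Fit on a :class:`~dadl.preprocess.LabeledDataset`'s train split,
    validating on its validation split.  Returns (model, history)."""
    if config is not None:
        model.set_params(**{k: v for k, v in asdict(config).items()
                            if k in model.get_params()})
    tr = dataset.split_frame("train")
    va = dataset.split_frame("val")
    val = (va["insert"].tolist(), va["label"].to_numpy()) if len(va) else None
    model.fit(tr["insert"].tolist(), tr["label"].to_numpy(),
              validation_data=val)
    return model, model.history_


def evaluate(model: FitnessCNN, dataset, split: str = "test") -> dict:
    """Accuracy and confusion counts at threshold 0.5, plus a per-insert-
    length accuracy breakdown."""
    frame = dataset.split_frame(split) if hasattr(dataset, "split_frame") else dataset
    if len(frame) == 0:
        raise ValueError("evaluation split is empty")
    inserts = frame["insert"].tolist()
    y = frame["label"].to_numpy()
    pred = model.predict(inserts)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    lengths = np.array([len(s) for s in inserts])
    by_len = {}
    for length in sorted(set(lengths.tolist())):
        mask = lengths == length
        by_len[int(length)] = float(np.mean(pred[mask] == y[mask]))
    return {
        "accuracy": float((tp + tn) / len(y)),
        "confusion": {"tp": tp, "tn": tn, "fp": fp, "fn": fn},
        "n": int(len(y)),
        "accuracy_by_length": by_len,
    }


def predict_fitness(model, inserts: Sequence[str]) -> np.ndarray:
    """Thin functional wrapper over ``model.predict_fitness``."""
    return model.predict_fitness(inserts)


def save_model(model: FitnessCNN, path) -> None:
    """Write weights plus config/encoder metadata to an ``.npz`` checkpoint."""
    model._check_fitted()
    meta = {k: v for k, v in model.get_params().items() if k != "template"}
    meta["template"] = asdict(model.template)
    np.savez(path, __meta__=json.dumps(meta), **model.net_.state_dict())


def load_model(path) -> FitnessCNN:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    template = PrecursorTemplate(**meta.pop("template"))
    est = FitnessCNN(template=template, **meta)
    est.build()
    est.net_.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return est
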