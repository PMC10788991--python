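"""The CNN-LSTM-SE classifier family and its ablation baselines.

Three variants are built from one config:

* ``cnn`` — a nine-layer 1-D CNN (3 conv, 3 max-pool, 3 dense);
* ``cnn_lstm`` — the conv stages feeding a stacked LSTM;
* ``cnn_lstm_se`` — additionally, squeeze-and-excitation channel attention
  after the second and third conv layers.  With the default 10-layer LSTM
  stack the counted components are 3 conv + 2 SE + 10 LSTM + 3 global
  average pools + 2 dense = 20.

`lstm_step_reference` and `se_block_reference` are deliberately literal,
step-by-step transcriptions of the gate equations and the
squeeze/excitation composition; unit tests hold the vectorized training
layers in :mod:`nyhagrade.nn` to these references.

`NYHAClassifier` wraps building + training behind the scikit-learn
estimator protocol, so it composes with ``clone``, pipelines and model
selection, and so cross-validation can also be run with any other
sklearn-compatible classifier.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn

__all__ = [
    "ModelConfig",
    "LSTMWeights",
    "SEParams",
    "build_model",
    "apply_dropout_scheme",
    "lstm_step_reference",
    "se_block_reference",
    "NYHAClassifier",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters for one variant.

    Conv filter counts, kernel widths and the pool size parameterize the
    three conv stages (defaults: a conventional 32/64/128 pyramid with
    kernels 7/5/3 and pool 2); `n_lstm_layers`/`lstm_hidden` size the
    recurrent stack; `se_reduction` is the SE bottleneck ratio r.
    Dropout scheme "A" trains without dropout; "B" drops 20% of the LSTM
    input and recurrent connections.
    """

    variant: str = "cnn_lstm_se"
    input_length: int = 1500
    n_classes: int = 4
    conv_filters: tuple = (32, 64, 128)
    kernel_sizes: tuple = (7, 5, 3)
    pool_size: int = 2
    n_lstm_layers: int = 10
    lstm_hidden: int = 32
    se_reduction: int = 8
    dropout_scheme: str = "A"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("cnn", "cnn_lstm", "cnn_lstm_se"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.dropout_scheme not in ("A", "B"):
            raise ValueError(f"dropout scheme must be 'A' or 'B', got {self.dropout_scheme!r}")

    @property
    def lstm_dropout_rates(self) -> tuple[float, float]:
        """(input, recurrent) dropout rates implied by the scheme."""
        return (0.0, 0.0) if self.dropout_scheme == "A" else (0.2, 0.2)


def apply_dropout_scheme(cfg: ModelConfig, scheme: str) -> ModelConfig:
    """Return a config with the given training scheme ('A': none, 'B': 20%/20%)."""
    if scheme not in ("A", "B"):
        raise ValueError(f"unknown scheme {scheme!r}")
    return dataclasses.replace(cfg, dropout_scheme=scheme)


def build_model(cfg: ModelConfig) -> nn.Network:
    """Instantiate the variant's network with seeded weight init."""
    rng = np.random.default_rng(cfg.seed)
    in_drop, rec_drop = cfg.lstm_dropout_rates
    return nn.Network(
        variant=cfg.variant,
        input_length=cfg.input_length,
        n_classes=cfg.n_classes,
        conv_filters=cfg.conv_filters,
        kernel_sizes=cfg.kernel_sizes,
        pool_size=cfg.pool_size,
        n_lstm_layers=cfg.n_lstm_layers,
        lstm_hidden=cfg.lstm_hidden,
        se_reduction=cfg.se_reduction,
        lstm_input_dropout=in_drop,
        lstm_recurrent_dropout=rec_drop,
        rng=rng,
    )


# --------------------------------------------------------------------------
# Literal reference implementations (oracles for the vectorized layers)
# --------------------------------------------------------------------------

@dataclass
class LSTMWeights:
    """Per-gate LSTM weights acting on the concatenation [h_{t-1}, x_t]."""

    K_f: np.ndarray
    K_i: np.ndarray
    K_o: np.ndarray
    K_c: np.ndarray
    Z_f: np.ndarray
    Z_i: np.ndarray
    Z_o: np.ndarray
    Z_c: np.ndarray

    def __post_init__(self) -> None:
        shape = self.K_f.shape
        for name in ("K_i", "K_o", "K_c"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != {shape}")
        h = shape[0]
        for name in ("Z_f", "Z_i", "Z_o", "Z_c"):
            if getattr(self, name).shape != (h,):
                raise ValueError(f"{name} must have length {h}")

    @property
    def hidden_size(self) -> int:
        return self.K_f.shape[0]

    @property
    def input_size(self) -> int:
        return self.K_f.shape[1] - self.K_f.shape[0]

    @classmethod
    def from_packed(cls, K: np.ndarray, Z: np.ndarray) -> "LSTMWeights":
        """Split a packed (4H, H+C) kernel / (4H,) bias in gate order f,i,o,c."""
        h = K.shape[0] // 4
        return cls(
            K_f=K[:h], K_i=K[h : 2 * h], K_o=K[2 * h : 3 * h], K_c=K[3 * h :],
            Z_f=Z[:h], Z_i=Z[h : 2 * h], Z_o=Z[2 * h : 3 * h], Z_c=Z[3 * h :],
        )

    @classmethod
    def random(cls, hidden_size: int, input_size: int, rng: np.random.Generator,
               scale: float = 0.3) -> "LSTMWeights":
        def w():
            return rng.normal(0.0, scale, size=(hidden_size, hidden_size + input_size))

        def b():
            return rng.normal(0.0, scale, size=hidden_size)

        return cls(K_f=w(), K_i=w(), K_o=w(), K_c=w(), Z_f=b(), Z_i=b(), Z_o=b(), Z_c=b())


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def lstm_step_reference(
    x: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, w: LSTMWeights
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update, written out gate by gate.

    f_t = sigmoid(K_f · [h_{t-1}, x_t] + Z_f)        (forget gate)
    i_t = sigmoid(K_i · [h_{t-1}, x_t] + Z_i)        (input gate)
    o_t = sigmoid(K_o · [h_{t-1}, x_t] + Z_o)        (output gate)
    c'_t = tanh(K_c · [h_{t-1}, x_t] + Z_c)          (candidate state)
    c_t = f_t * c_{t-1} + i_t * c'_t
    h_t = o_t * tanh(c_t)
    """
    x = np.asarray(x, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    c_prev = np.asarray(c_prev, dtype=float)
    if x.shape[-1] != w.input_size or h_prev.shape[-1] != w.hidden_size:
        raise ValueError(
            f"dimension mismatch: x has {x.shape[-1]} features (expected "
            f"{w.input_size}), h_prev has {h_prev.shape[-1]} (expected {w.hidden_size})"
        )
    concat = np.concatenate([h_prev, x], axis=-1)
    f_t = _sigmoid(concat @ w.K_f.T + w.Z_f)
    i_t = _sigmoid(concat @ w.K_i.T + w.Z_i)
    o_t = _sigmoid(concat @ w.K_o.T + w.Z_o)
    c_cand = np.tanh(concat @ w.K_c.T + w.Z_c)
    c_t = f_t * c_prev + i_t * c_cand
    h_t = o_t * np.tanh(c_t)
    return h_t, c_t


@dataclass
class SEParams:
    """Squeeze-and-excitation bottleneck parameters (C -> C/r -> C)."""

    fc1_w: np.ndarray  # (C/r, C)
    fc1_b: np.ndarray
    fc2_w: np.ndarray  # (C, C/r)
    fc2_b: np.ndarray

    def __post_init__(self) -> None:
        if self.fc2_w.shape[0] != self.fc1_w.shape[1]:
            raise ValueError("fc2 output width must equal the channel count C")

    @property
    def n_channels(self) -> int:
        return self.fc1_w.shape[1]


def se_block_reference(features: np.ndarray, params: SEParams) -> np.ndarray:
    """Squeeze-and-excitation on a (C, T) feature map, step by step.

    Squeeze: each channel is averaged over time to a scalar.  Excitation:
    the scalars pass through the two fully connected layers (ReLU between,
    sigmoid after) giving one weight in (0, 1) per channel.  Recalibration:
    every element of a channel is multiplied by that channel's weight.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] != params.n_channels:
        raise ValueError(
            f"expected (C={params.n_channels}, T) features, got {features.shape}"
        )
    squeeze = features.mean(axis=1)
    hidden = np.maximum(params.fc1_w @ squeeze + params.fc1_b, 0.0)
    weights = _sigmoid(params.fc2_w @ hidden + params.fc2_b)
    return features * weights[:, None]


# --------------------------------------------------------------------------
# Estimator
# --------------------------------------------------------------------------

class NYHAClassifier(BaseEstimator, ClassifierMixin):
    """NYHA-grade classifier over fixed-length normalized ECG segments.

    Follows the scikit-learn estimator protocol: constructor stores
    hyperparameters verbatim, ``fit(X, y)`` trains with Adam on
    class-weighted softmax cross-entropy, ``predict``/``predict_proba``
    evaluate deterministically (dropout off).

    Parameters mirror :class:`ModelConfig` plus the training settings
    (Adam, lr 0.001, 60 epochs, batch 32 by default; inverse-frequency
    class weights for the imbalanced cohort).
    """

    def __init__(
        self,
        variant: str = "cnn_lstm_se",
        conv_filters: tuple = (32, 64, 128),
        kernel_sizes: tuple = (7, 5, 3),
        pool_size: int = 2,
        n_lstm_layers: int = 10,
        lstm_hidden: int = 32,
        se_reduction: int = 8,
        dropout_scheme: str = "B",
        epochs: int = 60,
        batch_size: int = 32,
        learning_rate: float = 0.001,
        class_weighting: str = "inverse_frequency",
        seed: int = 0,
        verbose: int = 0,
    ):
        self.variant = variant
        self.conv_filters = conv_filters
        self.kernel_sizes = kernel_sizes
        self.pool_size = pool_size
        self.n_lstm_layers = n_lstm_layers
        self.lstm_hidden = lstm_hidden
        self.se_reduction = se_reduction
        self.dropout_scheme = dropout_scheme
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.class_weighting = class_weighting
        self.seed = seed
        self.verbose = verbose

    @classmethod
    def reduced(cls, variant: str = "cnn_lstm_se", **overrides) -> "NYHAClassifier":
        """Desk-scale configuration: narrow conv pyramid (8/16/32), pool 5,
        a 2-layer LSTM of width 24, scheme B, 10 epochs.  Trains a fold of
        the balanced synthetic study in seconds on one CPU."""
        params = dict(
            variant=variant, conv_filters=(8, 16, 32), kernel_sizes=(7, 5, 3),
            pool_size=5, n_lstm_layers=2, lstm_hidden=24, dropout_scheme="B",
            epochs=10, seed=0,
        )
        params.update(overrides)
        return cls(**params)

    def _model_config(self, input_length: int) -> ModelConfig:
        return ModelConfig(
            variant=self.variant,
            input_length=input_length,
            n_classes=len(self.classes_),
            conv_filters=tuple(self.conv_filters),
            kernel_sizes=tuple(self.kernel_sizes),
            pool_size=self.pool_size,
            n_lstm_layers=self.n_lstm_layers,
            lstm_hidden=self.lstm_hidden,
            se_reduction=self.se_reduction,
            dropout_scheme=self.dropout_scheme,
            seed=self.seed,
        )

    def fit(self, X, y, validation_data: Optional[tuple] = None) -> "NYHAClassifier":
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError(f"X must be 2-D (n_segments, segment_length), got {X.shape}")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        self.config_ = self._model_config(X.shape[1])
        self.network_ = build_model(self.config_)
        if self.class_weighting == "inverse_frequency":
            counts = np.bincount(y_idx, minlength=len(self.classes_))
            cw = len(y) / (len(self.classes_) * counts.astype(float))
        elif self.class_weighting == "none":
            cw = np.ones(len(self.classes_))
        else:
            raise ValueError(f"unknown class_weighting {self.class_weighting!r}")
        self.class_weight_ = cw
        sample_w = cw[y_idx]

        rng = np.random.default_rng(self.seed + 1)
        opt = nn.Adam(self.network_.params(), lr=self.learning_rate)
        n = len(X)
        history = {"loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []}
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses, hits, wtot = [], 0, 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                logits = self.network_.forward(X[idx], train=True)
                loss, dlogits = nn.weighted_cross_entropy(logits, y_idx[idx], sample_w[idx])
                self.network_.backward(dlogits)
                opt.step(self.network_.grads())
                losses.append(loss * len(idx))
                hits += int((logits.argmax(axis=1) == y_idx[idx]).sum())
                wtot += len(idx)
            history["loss"].append(sum(losses) / n)
            history["accuracy"].append(hits / n)
            if validation_data is not None:
                Xv, yv = validation_data
                pv = self._forward_eval(np.asarray(Xv, dtype=np.float32))
                yv_idx = np.searchsorted(self.classes_, np.asarray(yv))
                vloss, _ = nn.weighted_cross_entropy(pv, yv_idx)
                history["val_loss"].append(vloss)
                history["val_accuracy"].append(float((pv.argmax(1) == yv_idx).mean()))
            if self.verbose:
                print(
                    f"epoch {epoch + 1}/{self.epochs} "
                    f"loss={history['loss'][-1]:.4f} acc={history['accuracy'][-1]:.4f}"
                )
        self.history_ = history
        self.n_features_in_ = X.shape[1]
        return self

    def _forward_eval(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        out = []
        for start in range(0, len(X), batch):
            out.append(self.network_.forward(X[start : start + batch], train=False))
        return np.concatenate(out, axis=0)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        X = np.asarray(X, dtype=np.float32)
        return nn.softmax(self._forward_eval(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    # -- checkpointing -----------------------------------------------------
    def save(self, path) -> None:
        """Save hyperparameters, classes and weights to an .npz checkpoint."""
        check_is_fitted(self, "network_")
        import json

        arrays = {f"param_{i}": p for i, p in enumerate(self.network_.params())}
        meta = json.dumps(
            {
                "params": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in self.get_params().items()},
                "classes": [int(c) for c in self.classes_],
                "input_length": int(self.n_features_in_),
            }
        )
        np.savez_compressed(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8),
                            **arrays)

    @classmethod
    def load(cls, path) -> "NYHAClassifier":
        import json

        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            arrays = [data[f"param_{i}"] for i in range(len(data.files) - 1)]
        params = meta["params"]
        for key in ("conv_filters", "kernel_sizes"):
            params[key] = tuple(params[key])
        est = cls(**params)
        est.classes_ = np.asarray(meta["classes"])
        est.n_features_in_ = meta["input_length"]
        est.config_ = est._model_config(meta["input_length"])
        est.network_ = build_model(est.config_)
        for target, source in zip(est.network_.params(), arrays):
            target[...] = source
        est.history_ = {}
        return est
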