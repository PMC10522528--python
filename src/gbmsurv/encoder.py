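"""Autoencoder compression of the 120 connectome similarities.

A single hidden layer of 20 sigmoid units, linear decoder, mean-squared
reconstruction loss, trained by full-batch Adam (with reduce-on-plateau
learning-rate decay) on 80% of the supplied subjects with the remaining 20%
reserved purely for early-stopping termination.  After training, code
dimensions whose
activation variance across training subjects is negligible ("sparse"
features) are pruned; the survivors are relabeled FC1..FCm in original unit
order and become classifier inputs.

Inputs are standardized to zero mean / unit variance with training-split
statistics before fitting; the statistics travel with the model so encoding
a new subject applies the same scaling.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DataError, DegenerateDataError, ShapeError


@dataclass
class AutoencoderConfig:
    hidden_dim: int = 20
    val_fraction: float = 0.2
    learning_rate: float = 0.01
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    max_epochs: int = 5000
    patience: int = 150
    #: halve the learning rate when validation loss stalls this many epochs
    lr_plateau: int = 30
    #: a code unit is "sparse" when its activation variance is below this
    #: fraction of the most variable unit's variance
    sparsity_tol_ratio: float = 1e-4


@dataclass
class AutoencoderModel:
    """Fitted weights plus the preprocessing and bookkeeping they depend on."""

    input_dim: int
    hidden_dim: int
    W_enc: np.ndarray  # (hidden, input)
    b_enc: np.ndarray
    W_dec: np.ndarray  # (input, hidden)
    b_dec: np.ndarray
    input_mean: np.ndarray
    input_sd: np.ndarray
    training_log: list  # (epoch, train_mse, val_mse)
    best_epoch: int
    kept_features: tuple[int, ...] | None = None  # 0-based unit indices

    @property
    def feature_names(self) -> list[str]:
        kept = self.kept_features if self.kept_features is not None \
            else tuple(range(self.hidden_dim))
        return [f"FC{i + 1}" for i in range(len(kept))]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _standardize(X: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (X - mean) / sd


def _forward(model_or_params, Xs: np.ndarray):
    W1, b1, W2, b2 = model_or_params
    H = _sigmoid(Xs @ W1.T + b1)
    return H, H @ W2.T + b2


def fit_autoencoder(
    connectomes: np.ndarray,
    config: AutoencoderConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> AutoencoderModel:
    """Train the reconstruction autoencoder with validation early stopping.

    The 80/20 train/validation split, the weight initialization (uniform
    ±1/sqrt(fan-in)) and hence the fitted weights are fully determined by
    ``rng``.  The returned model carries the weights of the best-validation
    epoch, not the last one.
    """
    if config is None:
        config = AutoencoderConfig()
    rng = np.random.default_rng(rng)
    X = np.asarray(connectomes, dtype=float)
    if X.ndim != 2:
        raise ShapeError("connectomes must be a 2-D (subjects x features) matrix")
    if not np.all(np.isfinite(X)):
        raise DataError("connectome matrix contains non-finite values")
    n, d = X.shape
    if n < 10:
        raise ShapeError(f"need at least 10 subjects to fit the autoencoder, got {n}")

    perm = rng.permutation(n)
    n_val = max(int(round(config.val_fraction * n)), 1)
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    mean = X[train_idx].mean(axis=0)
    sd = X[train_idx].std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    Xtr = _standardize(X[train_idx], mean, sd)
    Xva = _standardize(X[val_idx], mean, sd)

    h = config.hidden_dim
    W1 = rng.uniform(-1, 1, (h, d)) / np.sqrt(d)
    b1 = np.zeros(h)
    W2 = rng.uniform(-1, 1, (d, h)) / np.sqrt(h)
    b2 = np.zeros(d)
    # full-batch Adam state
    m1 = [np.zeros_like(p) for p in (W1, b1, W2, b2)]
    m2 = [np.zeros_like(p) for p in (W1, b1, W2, b2)]

    best = {"val": np.inf, "epoch": -1, "params": None}
    log = []
    ntr = len(train_idx)
    stall = 0
    lr = config.learning_rate
    for epoch in range(config.max_epochs):
        H = _sigmoid(Xtr @ W1.T + b1)
        R = H @ W2.T + b2
        err = R - Xtr
        train_mse = float(np.mean(err * err))

        # backprop of the per-subject squared reconstruction error
        gR = err / ntr
        gW2 = gR.T @ H
        gb2 = gR.sum(axis=0)
        gH = gR @ W2
        gZ = gH * H * (1.0 - H)
        gW1 = gZ.T @ Xtr
        gb1 = gZ.sum(axis=0)

        b1c = 1.0 - config.adam_beta1 ** (epoch + 1)
        b2c = 1.0 - config.adam_beta2 ** (epoch + 1)
        for p, v1, v2, g in zip((W1, b1, W2, b2), m1, m2, (gW1, gb1, gW2, gb2)):
            v1 *= config.adam_beta1
            v1 += (1.0 - config.adam_beta1) * g
            v2 *= config.adam_beta2
            v2 += (1.0 - config.adam_beta2) * g * g
            p -= lr * (v1 / b1c) / (np.sqrt(v2 / b2c) + 1e-8)

        _, Rv = _forward((W1, b1, W2, b2), Xva)
        val_mse = float(np.mean((Rv - Xva) ** 2))
        log.append((epoch, train_mse, val_mse))

        if val_mse < best["val"] - 1e-12:
            best = {"val": val_mse, "epoch": epoch,
                    "params": tuple(p.copy() for p in (W1, b1, W2, b2))}
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
            if stall % config.lr_plateau == 0:
                lr *= 0.5

    W1, b1, W2, b2 = best["params"]
    return AutoencoderModel(
        input_dim=d, hidden_dim=h,
        W_enc=W1, b_enc=b1, W_dec=W2, b_dec=b2,
        input_mean=mean, input_sd=sd,
        training_log=log, best_epoch=best["epoch"],
    )


def encode(model: AutoencoderModel, connectome: np.ndarray) -> np.ndarray:
    """Hidden-layer activations for one subject or a batch, kept units only."""
    X = np.asarray(connectome, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != model.input_dim:
        raise ShapeError(f"expected {model.input_dim} features, got {X.shape[1]}")
    Xs = _standardize(X, model.input_mean, model.input_sd)
    H = _sigmoid(Xs @ model.W_enc.T + model.b_enc)
    if model.kept_features is not None:
        H = H[:, list(model.kept_features)]
    return H[0] if single else H


def decode(model: AutoencoderModel, code_full: np.ndarray) -> np.ndarray:
    """Reconstruct (in original units) from a full 20-unit code."""
    R = code_full @ model.W_dec.T + model.b_dec
    return R * model.input_sd + model.input_mean


def reconstruct(model: AutoencoderModel, connectome: np.ndarray) -> np.ndarray:
    X = np.asarray(connectome, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    Xs = _standardize(X, model.input_mean, model.input_sd)
    H = _sigmoid(Xs @ model.W_enc.T + model.b_enc)
    R = decode(model, H)
    return R[0] if single else R


def prune_sparse_features(model: AutoencoderModel, connectomes: np.ndarray) -> AutoencoderModel:
    """Drop code units whose activation barely varies across subjects.

    The variance of each unit's activation is measured over the supplied
    (training) subjects; units below ``sparsity_tol_ratio`` times the
    largest unit variance are removed.  Pruning only restricts which units
    :func:`encode` reports — surviving activations are unchanged.
    """
    tol_ratio = AutoencoderConfig().sparsity_tol_ratio
    return prune_sparse_features_with_tol(model, connectomes, tol_ratio)


def prune_sparse_features_with_tol(
    model: AutoencoderModel, connectomes: np.ndarray, tol_ratio: float
) -> AutoencoderModel:
    full = dataclasses.replace(model, kept_features=None)
    H = encode(full, np.asarray(connectomes, float))
    var = H.var(axis=0)
    tol = tol_ratio * var.max()
    kept = tuple(int(i) for i in range(model.hidden_dim) if var[i] > tol)
    if not kept:
        raise DegenerateDataError("all code units fall below the sparsity tolerance")
    return dataclasses.replace(model, kept_features=kept)


# ---------------------------------------------------------------------------
# serialization: JSON manifest + plain-text arrays
# ---------------------------------------------------------------------------

_ARRAY_FIELDS = ("W_enc", "b_enc", "W_dec", "b_dec", "input_mean", "input_sd")


def save_model(model: AutoencoderModel, out_dir: str | Path) -> str:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in _ARRAY_FIELDS:
        np.savetxt(out / f"{name}.txt", np.atleast_2d(getattr(model, name)))
    meta = {
        "input_dim": model.input_dim,
        "hidden_dim": model.hidden_dim,
        "best_epoch": model.best_epoch,
        "kept_features": list(model.kept_features) if model.kept_features is not None else None,
        "training_log": [[int(e), tr, va] for e, tr, va in model.training_log],
    }
    (out / "autoencoder.json").write_text(json.dumps(meta))
    return str(out)


def load_model(model_dir: str | Path) -> AutoencoderModel:
    d = Path(model_dir)
    meta = json.loads((d / "autoencoder.json").read_text())
    arrays = {}
    for name in _ARRAY_FIELDS:
        a = np.loadtxt(d / f"{name}.txt")
        arrays[name] = a if name.startswith("W_") else np.ravel(a)
    kept = meta["kept_features"]
    return AutoencoderModel(
        input_dim=meta["input_dim"], hidden_dim=meta["hidden_dim"],
        training_log=[tuple(x) for x in meta["training_log"]],
        best_epoch=meta["best_epoch"],
        kept_features=tuple(kept) if kept is not None else None,
        **arrays,
    )
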