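"""Feed-forward network predicting breeding values from phenotypic features.

A deliberately small regressor: 4 hidden layers of 10 tanh units and a
linear output (451 parameters at 5 inputs), trained by mini-batch Adam on
z-scored features with EBVs as labels.  The model is implemented with
plain dense-matrix forward/backward passes so that training is exactly
reproducible for a fixed seed and the fitted model serialises to JSON.

Default hyperparameters: learning rate 1e-3, Adam (beta1=0.9, beta2=0.999,
eps=1e-8), 500 epochs, batch size 10, validation split 0.2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AnnError",
    "MLPConfig",
    "Dataset",
    "EvalMetrics",
    "MLPModel",
    "prepare_dataset",
    "train_mlp",
    "predict",
    "evaluate",
    "save_model",
    "load_model",
]


class AnnError(ValueError):
    pass


@dataclass
class MLPConfig:
    hidden_layers: int = 4
    units_per_layer: int = 10
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    epochs: int = 500
    batch_size: int = 10
    validation_split: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.hidden_layers, self.units_per_layer, self.epochs, self.batch_size) <= 0:
            raise AnnError("architecture and schedule settings must be positive")
        if not (0.0 < self.validation_split < 1.0):
            raise AnnError("validation_split must lie in (0, 1)")
        if self.learning_rate <= 0:
            raise AnnError("learning rate must be positive")


@dataclass
class Dataset:
    features: np.ndarray  # n x p, scaled
    labels: np.ndarray    # n, in original (label) units
    feature_scaler: tuple[np.ndarray, np.ndarray]  # per-column (mean, sd) of train
    label_scaler: tuple[float, float]              # (mean, sd) of train labels
    feature_names: list[str] = field(default_factory=list)


@dataclass
class EvalMetrics:
    pearson_r: float
    mae: float
    mse: float
    rmse: float

    @property
    def pearson_r_x100(self) -> float:
        return 100.0 * self.pearson_r


@dataclass
class MLPModel:
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    feature_scaler: tuple[np.ndarray, np.ndarray]
    label_scaler: tuple[float, float]
    config: MLPConfig
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)


def prepare_dataset(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    test_fraction: float = 0.2,
    outlier_sd: float = 3.0,
    feature_names: Sequence[str] | None = None,
) -> tuple[Dataset, Dataset]:
    """Clean, split and scale a feature/label table.

    Rows with any missing value are dropped, then rows with any feature or
    label beyond ``outlier_sd`` column standard deviations of the column
    mean.  Constant feature columns are dropped (their sd is zero).  The
    survivors are shuffled with the given seed and split
    (1-test_fraction)/test_fraction; z-score scaling of features and
    labels is fitted on the training portion only and applied to both.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise AnnError("features must be n x p and labels length n")
    if X.shape[0] < 50:
        raise AnnError("need at least 50 rows")
    names = list(feature_names) if feature_names is not None else [
        f"x{j}" for j in range(X.shape[1])
    ]

    keep = np.isfinite(X).all(axis=1) & np.isfinite(y)
    X, y = X[keep], y[keep]

    cols = np.concatenate([X, y[:, None]], axis=1)
    mu = cols.mean(axis=0)
    sd = cols.std(axis=0)
    ok = np.ones(len(X), dtype=bool)
    for j in range(cols.shape[1]):
        if sd[j] > 0:
            ok &= np.abs(cols[:, j] - mu[j]) <= outlier_sd * sd[j]
    X, y = X[ok], y[ok]

    col_sd = X.std(axis=0)
    retained = col_sd > 0
    if not retained.all():
        import warnings
        dropped = [names[j] for j in np.flatnonzero(~retained)]
        warnings.warn(f"dropping constant feature column(s): {', '.join(dropped)}")
        X = X[:, retained]
        names = [n for n, r in zip(names, retained) if r]

    if len(X) < 20:
        raise AnnError(f"only {len(X)} rows survive cleaning; need at least 20")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(X))
    n_test = max(1, int(round(test_fraction * len(X))))
    test_idx, train_idx = order[:n_test], order[n_test:]

    f_mu = X[train_idx].mean(axis=0)
    f_sd = X[train_idx].std(axis=0)
    f_sd[f_sd == 0] = 1.0
    l_mu = float(y[train_idx].mean())
    l_sd = float(y[train_idx].std()) or 1.0

    def make(idx) -> Dataset:
        return Dataset(
            features=(X[idx] - f_mu) / f_sd,
            labels=y[idx],
            feature_scaler=(f_mu, f_sd),
            label_scaler=(l_mu, l_sd),
            feature_names=names,
        )

    return make(train_idx), make(test_idx)


def _init_params(cfg: MLPConfig, p: int, rng: np.random.Generator):
    sizes = [p] + [cfg.units_per_layer] * cfg.hidden_layers + [1]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def _forward(weights, biases, X):
    """Returns activations per layer; tanh hidden, linear output."""
    acts = [X]
    h = X
    last = len(weights) - 1
    for i, (W, b) in enumerate(zip(weights, biases)):
        z = h @ W + b
        h = z if i == last else np.tanh(z)
        acts.append(h)
    return acts


def train_mlp(train: Dataset, cfg: MLPConfig, validation: Dataset | None = None) -> MLPModel:
    """Train by mini-batch Adam on scaled features and z-scored labels.

    The internal validation split (``cfg.validation_split`` of the
    training rows, seeded) monitors generalisation; per-epoch training and
    validation MSE are recorded on the model.  Training diverging to NaN
    raises with advice to lower the learning rate.  Runs are
    bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    X = train.features
    l_mu, l_sd = train.label_scaler
    y = (train.labels - l_mu) / l_sd

    if validation is None:
        n_val = max(1, int(round(cfg.validation_split * len(X))))
        order = rng.permutation(len(X))
        val_idx, fit_idx = order[:n_val], order[n_val:]
        Xv, yv = X[val_idx], y[val_idx]
        Xf, yf = X[fit_idx], y[fit_idx]
    else:
        Xf, yf = X, y
        Xv = validation.features
        yv = (validation.labels - l_mu) / l_sd

    weights, biases = _init_params(cfg, X.shape[1], rng)
    mW = [np.zeros_like(W) for W in weights]
    vW = [np.zeros_like(W) for W in weights]
    mb = [np.zeros_like(b) for b in biases]
    vb = [np.zeros_like(b) for b in biases]

    model = MLPModel(weights=weights, biases=biases,
                     feature_scaler=train.feature_scaler,
                     label_scaler=train.label_scaler, config=cfg)
    t = 0
    n = len(Xf)
    last = len(weights) - 1
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            xb, yb = Xf[idx], yf[idx]
            acts = _forward(weights, biases, xb)
            pred = acts[-1][:, 0]
            # d(MSE)/d(pred), MSE averaged over the batch
            delta = (2.0 / len(idx)) * (pred - yb)[:, None]
            t += 1
            for i in range(last, -1, -1):
                gW = acts[i].T @ delta
                gb = delta.sum(axis=0)
                if i > 0:
                    delta = (delta @ weights[i].T) * (1.0 - acts[i] ** 2)
                for g, W, m, v in ((gW, weights[i], mW[i], vW[i]),
                                   (gb, biases[i], mb[i], vb[i])):
                    m *= cfg.beta1
                    m += (1 - cfg.beta1) * g
                    v *= cfg.beta2
                    v += (1 - cfg.beta2) * g * g
                    mhat = m / (1 - cfg.beta1 ** t)
                    vhat = v / (1 - cfg.beta2 ** t)
                    W -= cfg.learning_rate * mhat / (np.sqrt(vhat) + cfg.eps)
        tr_loss = float(np.mean((_forward(weights, biases, Xf)[-1][:, 0] - yf) ** 2))
        va_loss = float(np.mean((_forward(weights, biases, Xv)[-1][:, 0] - yv) ** 2))
        if not (np.isfinite(tr_loss) and np.isfinite(va_loss)):
            raise AnnError(
                "training diverged (loss is NaN/inf); try a lower learning rate"
            )
        model.train_loss.append(tr_loss)
        model.val_loss.append(va_loss)
    return model


def predict(model: MLPModel, features: np.ndarray, scaled: bool = False) -> np.ndarray:
    """Deterministic forward pass; output back on the label scale.

    ``features`` are raw by default and are standardised with the stored
    training scaler; pass ``scaled=True`` for features already z-scored
    (e.g. a Dataset's own matrix).
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    p = model.weights[0].shape[0]
    if X.shape[1] != p:
        raise AnnError(f"model expects {p} features, got {X.shape[1]}")
    if not scaled:
        f_mu, f_sd = model.feature_scaler
        X = (X - f_mu) / f_sd
    z = _forward(model.weights, model.biases, X)[-1][:, 0]
    l_mu, l_sd = model.label_scaler
    return z * l_sd + l_mu


def evaluate(predictions: np.ndarray, labels: np.ndarray) -> EvalMetrics:
    """Pearson r, MAE, MSE and RMSE by their standard definitions."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.size != y.size or p.size < 2:
        raise AnnError("need equal-length prediction/label vectors of length >= 2")
    if np.std(y) == 0:
        raise AnnError("labels are constant; correlation undefined")
    r = float(np.corrcoef(p, y)[0, 1])
    err = p - y
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err ** 2))
    return EvalMetrics(pearson_r=r, mae=mae, mse=mse, rmse=float(np.sqrt(mse)))


# ---------------------------------------------------------------------------
# serialisation

def save_model(model: MLPModel, path: str | Path) -> None:
    blob = {
        "config": asdict(model.config),
        "weights": [W.tolist() for W in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "feature_scaler": [model.feature_scaler[0].tolist(), model.feature_scaler[1].tolist()],
        "label_scaler": list(model.label_scaler),
        "train_loss": model.train_loss,
        "val_loss": model.val_loss,
    }
    Path(path).write_text(json.dumps(blob))


def load_model(path: str | Path) -> MLPModel:
    blob = json.loads(Path(path).read_text())
    return MLPModel(
        weights=[np.array(W) for W in blob["weights"]],
        biases=[np.array(b) for b in blob["biases"]],
        feature_scaler=(np.array(blob["feature_scaler"][0]), np.array(blob["feature_scaler"][1])),
        label_scaler=tuple(blob["label_scaler"]),
        config=MLPConfig(**blob["config"]),
        train_loss=blob["train_loss"],
        val_loss=blob["val_loss"],
    )
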