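"""Backpropagation network inverting vegetation indices to SPAD.

A single-hidden-layer feed-forward regression network (18 tanh units, linear
output) trained by full-batch gradient descent on mean squared error — the
literal backpropagation algorithm. Defaults follow the inversion protocol:
learning rate 0.001, 50 epochs, eight random 70/30 re-splits (84 train / 35
validation at n = 119), with fits scored by Pearson r, R² (= r²), RMSE and
mean absolute relative error (RE).

Features and the response are standardized internally using training-split
statistics only; predictions are returned on the raw SPAD scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Hyperparams:
    n_hidden: int = 18
    learning_rate: float = 0.001
    epochs: int = 50
    activation: str = "tanh"  # "tanh" | "sigmoid"


@dataclass
class InversionModel:
    feature_names: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    w1: np.ndarray  # (n_features, n_hidden)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden,)
    b2: float
    hyperparams: Hyperparams
    seed: int
    loss_trajectory: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_json(self) -> str:
        d = {
            "feature_names": self.feature_names,
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "hyperparams": vars(self.hyperparams),
            "seed": self.seed,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "InversionModel":
        d = json.loads(text)
        return cls(
            feature_names=d["feature_names"],
            x_mean=np.asarray(d["x_mean"], dtype=float),
            x_sd=np.asarray(d["x_sd"], dtype=float),
            y_mean=float(d["y_mean"]),
            y_sd=float(d["y_sd"]),
            w1=np.asarray(d["w1"], dtype=float),
            b1=np.asarray(d["b1"], dtype=float),
            w2=np.asarray(d["w2"], dtype=float),
            b2=float(d["b2"]),
            hyperparams=Hyperparams(**d["hyperparams"]),
            seed=int(d["seed"]),
        )


def _activation(name):
    if name == "tanh":
        return np.tanh, lambda a: 1.0 - a**2
    if name == "sigmoid":
        sig = lambda z: 1.0 / (1.0 + np.exp(-z))  # noqa: E731
        return sig, lambda a: a * (1.0 - a)
    raise ValueError(f"unknown activation {name!r}")


def _as_matrix(features, feature_names=None):
    if isinstance(features, pd.DataFrame):
        names = feature_names or list(features.columns)
        missing = [c for c in names if c not in features.columns]
        if missing:
            raise KeyError(f"missing feature columns: {missing}")
        return features[names].to_numpy(dtype=float), names
    X = np.asarray(features, dtype=float)
    names = feature_names or [f"x{i}" for i in range(X.shape[1])]
    return X, names


def train_inversion_model(
    features,
    spad,
    hyperparams: Hyperparams | None = None,
    seed: int = 0,
) -> InversionModel:
    """Fit the BP network by full-batch gradient descent on MSE.

    Weight initialization is seeded (scaled normal); the loss trajectory on
    the standardized training data is recorded per epoch. Divergence
    (non-finite loss) raises, naming the epoch.
    """
    hp = hyperparams or Hyperparams()
    X, names = _as_matrix(features)
    y = np.asarray(spad, dtype=float)
    n, p = X.shape
    if n < 20:
        raise ValueError(f"need n >= 20 training samples, got {n}")
    x_mean, x_sd = X.mean(axis=0), X.std(axis=0)
    x_sd = np.where(x_sd == 0, 1.0, x_sd)
    y_mean, y_sd = float(y.mean()), float(y.std())
    rng = np.random.default_rng(seed)
    h = hp.n_hidden
    w1 = rng.normal(0.0, 1.0 / np.sqrt(p), size=(p, h))
    b1 = np.zeros(h)
    w2 = rng.normal(0.0, 1.0 / np.sqrt(h), size=h)
    b2 = 0.0
    act, dact = _activation(hp.activation)

    if y_sd == 0:
        # degenerate constant target: the MSE optimum is the constant
        # prediction, reached exactly by zeroing the output layer
        return InversionModel(
            feature_names=list(names),
            x_mean=x_mean, x_sd=x_sd, y_mean=y_mean, y_sd=1.0,
            w1=w1, b1=b1, w2=np.zeros(h), b2=0.0,
            hyperparams=hp, seed=seed, loss_trajectory=np.zeros(1),
        )
    Xs = (X - x_mean) / x_sd
    ys = (y - y_mean) / y_sd

    losses = np.empty(hp.epochs + 1)
    for epoch in range(hp.epochs + 1):
        a = act(Xs @ w1 + b1)  # (n, h)
        pred = a @ w2 + b2
        err = pred - ys
        loss = float(np.mean(err**2))
        losses[epoch] = loss
        if not np.isfinite(loss):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        if epoch == hp.epochs:
            break
        # backpropagation of the MSE gradient
        g_pred = 2.0 * err / n
        g_w2 = a.T @ g_pred
        g_b2 = g_pred.sum()
        g_a = np.outer(g_pred, w2) * dact(a)
        g_w1 = Xs.T @ g_a
        g_b1 = g_a.sum(axis=0)
        lr = hp.learning_rate
        w1 -= lr * g_w1
        b1 -= lr * g_b1
        w2 -= lr * g_w2
        b2 -= lr * g_b2

    return InversionModel(
        feature_names=list(names),
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
        w1=w1,
        b1=b1,
        w2=w2,
        b2=float(b2),
        hyperparams=hp,
        seed=seed,
        loss_trajectory=losses,
    )


def predict_spad(model: InversionModel, features) -> np.ndarray:
    """Deterministic forward pass; output on the raw SPAD scale."""
    X, _ = _as_matrix(features, model.feature_names)
    Xs = (X - model.x_mean) / model.x_sd
    act, _ = _activation(model.hyperparams.activation)
    pred_s = act(Xs @ model.w1 + model.b1) @ model.w2 + model.b2
    return pred_s * model.y_sd + model.y_mean


def evaluate_predictions(obs, pred) -> dict[str, float]:
    """Pearson r, R² (= r²), RMSE and mean absolute relative error.

    The coefficient-of-determination form of R² is also returned
    (``r2_cod``), alongside RMSE on the z-score scale of the observations
    (``rmse_std``) for comparability across cells.
    """
    o = np.asarray(obs, dtype=float)
    p = np.asarray(pred, dtype=float)
    if o.shape != p.shape:
        raise ValueError("obs and pred must have equal length")
    n = o.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rmse = float(np.sqrt(np.mean((p - o) ** 2)))
    if np.any(o == 0):
        re = float(np.mean(np.abs(p - o)[o != 0] / np.abs(o[o != 0])))
    else:
        re = float(np.mean(np.abs(p - o) / np.abs(o)))
    so, sp = o.std(), p.std()
    if so == 0 or sp == 0:
        r = np.nan
    else:
        r = float(((o - o.mean()) * (p - p.mean())).mean() / (so * sp))
        r = min(1.0, max(-1.0, r))
    sst = float(np.sum((o - o.mean()) ** 2))
    r2_cod = 1.0 - float(np.sum((p - o) ** 2)) / sst if sst > 0 else np.nan
    return {
        "r": r,
        "r2": r**2 if np.isfinite(r) else np.nan,
        "rmse": rmse,
        "re": re,
        "r2_cod": r2_cod,
        "rmse_std": rmse / so if so > 0 else np.nan,
    }


def replicate_fit(
    features,
    spad,
    n_replicates: int = 8,
    train_fraction: float = 0.7,
    hyperparams: Hyperparams | None = None,
    seed: int = 0,
    mode: str = "resplit",
) -> pd.DataFrame:
    """Train/validate over repeated random 70/30 splits.

    ``mode="resplit"`` draws an independent split per replicate (default);
    ``mode="restart"`` keeps one split and re-initializes the weights. At
    n = 119 the split is 84 train / 35 validation. Returns one metrics row
    per replicate plus a ``"mean"`` row.
    """
    X, names = _as_matrix(features)
    y = np.asarray(spad, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("need n >= 10 samples")
    n_train = int(np.ceil(train_fraction * n))  # 84 train / 35 val at n=119
    rng = np.random.default_rng(seed)
    if mode not in ("resplit", "restart"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    perm0 = rng.permutation(n)
    for rep in range(1, n_replicates + 1):
        perm = perm0 if mode == "restart" else rng.permutation(n)
        tr, va = perm[:n_train], perm[n_train:]
        model = train_inversion_model(
            pd.DataFrame(X[tr], columns=names),
            y[tr],
            hyperparams=hyperparams,
            seed=seed + rep,
        )
        pred = predict_spad(model, pd.DataFrame(X[va], columns=names))
        m = evaluate_predictions(y[va], pred)
        rows.append(
            {
                "replicate": rep,
                "n_train": len(tr),
                "n_val": len(va),
                **m,
                "train_idx": tuple(int(i) for i in tr),
                "val_idx": tuple(int(i) for i in va),
            }
        )
    report = pd.DataFrame(rows)
    mean_row = report.drop(columns="replicate").mean(numeric_only=True)
    mean_row["replicate"] = "mean"
    return pd.concat([report, mean_row.to_frame().T], ignore_index=True)
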