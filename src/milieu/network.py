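"""Feed-forward "wave" regression of the health behavior index.

:class:`MLPWaveRegressor` is a deliberately small single-hidden-layer
perceptron (tanh hidden units, linear output) trained with full-batch Adam on
mean-squared error, early-stopped on a held-out validation split stratified by
target quartiles, with the best-of-``restarts`` weights (by validation error)
retained.  Everything is deterministic given the data and ``random_state``;
when the design matrix carries column names, initialization seeds are derived
from the *sorted* names so predictions are invariant to column order.

:func:`run_prediction_waves` fits the network once per predictor block — the
five "test waves" — plus a sixth *saturated* wave on all blocks concatenated,
and reports each wave's per-participant estimates of the index together with
the Pearson correlation between estimates and the actual index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.utils.validation import check_is_fitted

from ._seeds import derive_seed
from .data import BLOCK_NAMES, PredictorBlocks

logger = logging.getLogger(__name__)

WAVE_NAMES = BLOCK_NAMES + ("saturated",)


class TrainingError(RuntimeError):
    """Training diverged (non-finite loss)."""


def _activation(name: str):
    if name == "tanh":
        return np.tanh, lambda a: 1.0 - a * a  # derivative in terms of activation
    if name == "logistic":
        return (lambda z: 1.0 / (1.0 + np.exp(-z))), lambda a: a * (1.0 - a)
    raise ValueError(f"unknown activation {name!r}")


class MLPWaveRegressor(RegressorMixin, BaseEstimator):
    """Small early-stopped multilayer perceptron for index regression.

    Parameters
    ----------
    hidden_units : int, default 5
        Width of the single hidden layer.
    activation : {"tanh", "logistic"}, default "tanh"
        Hidden nonlinearity; the output unit is linear.
    max_epochs : int, default 2000
        Upper bound on full-batch Adam epochs per restart.
    learning_rate : float, default 0.05
        Adam step size.
    validation_fraction : float, default 0.2
        Fraction of rows held out for early stopping, sampled within target
        quartiles so the split is balanced on the outcome.
    patience : int, default 50
        Epochs without validation improvement before stopping.
    restarts : int, default 5
        Independent seeded initializations; the weights with the lowest
        validation MSE across restarts are kept.
    random_state : int, default 0
        Master seed.  With named columns the effective seed also hashes the
        sorted column names, making fits invariant to column order.
    """

    def __init__(
        self,
        hidden_units: int = 5,
        activation: str = "tanh",
        max_epochs: int = 2000,
        learning_rate: float = 0.05,
        validation_fraction: float = 0.2,
        patience: int = 50,
        restarts: int = 5,
        random_state: int = 0,
        tol: float = 1e-7,
    ):
        self.hidden_units = hidden_units
        self.activation = activation
        self.max_epochs = max_epochs
        self.learning_rate = learning_rate
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.restarts = restarts
        self.random_state = random_state
        self.tol = tol

    # -- helpers ---------------------------------------------------------
    def _canonical(self, X) -> tuple[np.ndarray, list | None]:
        if isinstance(X, pd.DataFrame):
            order = sorted(X.columns.astype(str))
            return X[order].to_numpy(dtype=float), order
        return np.asarray(X, dtype=float), None

    def _stratified_split(self, y: np.ndarray, rng: np.random.Generator):
        """Validation indices drawn within target quartiles."""
        n = len(y)
        n_val = max(1, int(round(self.validation_fraction * n)))
        ranks = stats.rankdata(y, method="ordinal") - 1
        quartile = (ranks * 4) // n
        val: list[int] = []
        for q in range(4):
            idx = np.where(quartile == q)[0]
            take = int(round(len(idx) * n_val / n))
            if len(idx):
                val.extend(rng.permutation(idx)[:take].tolist())
        val_idx = np.sort(np.asarray(val, dtype=int))
        train_idx = np.setdiff1d(np.arange(n), val_idx)
        if len(train_idx) < 10:
            raise ValueError("validation_fraction leaves fewer than 10 training rows")
        return train_idx, val_idx

    def _init_weights(self, d: int, rng: np.random.Generator):
        h = self.hidden_units
        w1 = rng.normal(scale=1.0 / np.sqrt(d), size=(d, h))
        b1 = np.zeros(h)
        w2 = rng.normal(scale=1.0 / np.sqrt(h), size=(h, 1))
        b2 = np.zeros(1)
        return [w1, b1, w2, b2]

    def _forward(self, X: np.ndarray, weights) -> tuple[np.ndarray, np.ndarray]:
        act, _ = _activation(self.activation)
        w1, b1, w2, b2 = weights
        hidden = act(X @ w1 + b1)
        return hidden, (hidden @ w2 + b2).ravel()

    def _train_once(self, Xt, yt, Xv, yv, seed: int):
        rng = np.random.default_rng(seed)
        weights = self._init_weights(Xt.shape[1], rng)
        _, dact = _activation(self.activation)
        m = [np.zeros_like(w) for w in weights]
        v = [np.zeros_like(w) for w in weights]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        best = {"mse": np.inf, "weights": [w.copy() for w in weights], "epoch": 0}
        since_best = 0
        n = len(yt)
        for epoch in range(1, self.max_epochs + 1):
            w1, b1, w2, b2 = weights
            hidden, pred = self._forward(Xt, weights)
            err = pred - yt
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch} (seed {seed})")
            g_out = (2.0 / n) * err[:, None]  # d(mse)/d(pred)
            grads = [
                Xt.T @ ((g_out @ w2.T) * dact(hidden)),
                ((g_out @ w2.T) * dact(hidden)).sum(axis=0),
                hidden.T @ g_out,
                g_out.sum(axis=0),
            ]
            for i, g in enumerate(grads):
                m[i] = beta1 * m[i] + (1 - beta1) * g
                v[i] = beta2 * v[i] + (1 - beta2) * g * g
                mhat = m[i] / (1 - beta1**epoch)
                vhat = v[i] / (1 - beta2**epoch)
                weights[i] = weights[i] - self.learning_rate * mhat / (np.sqrt(vhat) + eps)
            _, val_pred = self._forward(Xv, weights)
            val_mse = float(np.mean((val_pred - yv) ** 2))
            if val_mse < best["mse"] - self.tol:
                best = {"mse": val_mse, "weights": [w.copy() for w in weights], "epoch": epoch}
                since_best = 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        return best

    # -- sklearn interface ----------------------------------------------
    def fit(self, X, y):
        Xc, names = self._canonical(X)
        y = np.asarray(y, dtype=float).ravel()
        if Xc.ndim != 2 or Xc.shape[1] == 0:
            raise ValueError("X must be a 2-d matrix with at least one column")
        if Xc.shape[0] != len(y):
            raise ValueError("X and y row counts differ")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if names is not None:
            self.feature_names_in_ = np.asarray(names, dtype=object)
            seed0 = derive_seed(self.random_state, "mlp", *names)
        else:
            self.feature_names_in_ = None
            seed0 = derive_seed(self.random_state, "mlp", Xc.shape[1])
        rng = np.random.default_rng(seed0)
        train_idx, val_idx = self._stratified_split(y, rng)
        Xt, yt = Xc[train_idx], y[train_idx]
        Xv, yv = Xc[val_idx], y[val_idx]
        best, best_restart = None, -1
        for r in range(self.restarts):
            result = self._train_once(Xt, yt, Xv, yv, derive_seed(seed0, "restart", r))
            if best is None or result["mse"] < best["mse"]:
                best, best_restart = result, r
        self.weights_ = best["weights"]
        self.best_val_mse_ = best["mse"]
        self.n_iter_ = best["epoch"]
        self.best_restart_ = best_restart
        self.train_idx_, self.val_idx_ = train_idx, val_idx
        self.n_features_in_ = Xc.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        if isinstance(X, pd.DataFrame) and self.feature_names_in_ is not None:
            Xc = X[list(self.feature_names_in_)].to_numpy(dtype=float)
        else:
            Xc = np.asarray(X, dtype=float)
        if Xc.shape[1] != self.n_features_in_:
            raise ValueError(f"X has {Xc.shape[1]} columns, model expects {self.n_features_in_}")
        return self._forward(Xc, self.weights_)[1]

    def hidden_activations(self, X) -> np.ndarray:
        """Hidden-layer outputs per participant (for cluster feature modes)."""
        check_is_fitted(self, "weights_")
        if isinstance(X, pd.DataFrame) and self.feature_names_in_ is not None:
            Xc = X[list(self.feature_names_in_)].to_numpy(dtype=float)
        else:
            Xc = np.asarray(X, dtype=float)
        return self._forward(Xc, self.weights_)[0]

    def to_json_dict(self) -> dict:
        check_is_fitted(self, "weights_")
        return {
            "params": self.get_params(),
            "feature_names": None if self.feature_names_in_ is None else list(self.feature_names_in_),
            "weights": [w.tolist() for w in self.weights_],
            "best_val_mse": self.best_val_mse_,
            "n_iter": self.n_iter_,
            "best_restart": self.best_restart_,
        }


def train_network(X, y, **params) -> MLPWaveRegressor:
    """Functional wrapper: fit an :class:`MLPWaveRegressor`."""
    return MLPWaveRegressor(**params).fit(X, y)


def predict(model: MLPWaveRegressor, X) -> np.ndarray:
    return model.predict(X)


# ---------------------------------------------------------------------------
# prediction waves
# ---------------------------------------------------------------------------


@dataclass
class WaveResult:
    """One test wave: estimates of the index from a single predictor block."""

    wave_name: str
    estimates: np.ndarray
    r_with_target: float
    model: MLPWaveRegressor | None = None


@dataclass
class WaveSet:
    """The six waves: five per-block plus the saturated model, in order."""

    waves: list[WaveResult] = field(default_factory=list)

    def __post_init__(self):
        names = tuple(w.wave_name for w in self.waves)
        if sorted(names) != sorted(set(names)):
            raise ValueError("duplicate wave names")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(w.wave_name for w in self.waves)

    def __getitem__(self, name: str) -> WaveResult:
        for w in self.waves:
            if w.wave_name == name:
                return w
        raise KeyError(name)

    def __iter__(self):
        return iter(self.waves)

    def __len__(self) -> int:
        return len(self.waves)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(stats.pearsonr(a, b).statistic)


def run_prediction_waves(
    blocks: PredictorBlocks,
    y,
    base_estimator: MLPWaveRegressor | None = None,
    random_state: int = 0,
    holdout_estimates: bool = False,
    n_folds: int = 5,
) -> WaveSet:
    """Fit one wave per predictor block plus the saturated wave.

    Estimates are reported for every participant from the early-stopped
    network fitted on the full sample (the index regressions use one estimate
    per participant).  With ``holdout_estimates=True`` the estimates are
    instead out-of-fold predictions from a seeded K-fold, a cross-validated
    sensitivity mode.
    """
    base = base_estimator if base_estimator is not None else MLPWaveRegressor()
    y = np.asarray(y, dtype=float).ravel()
    designs = {name: blocks[name] for name in blocks.names}
    designs["saturated"] = blocks.saturated()
    waves = []
    for name in tuple(blocks.names) + ("saturated",):
        X = designs[name]
        est = clone(base)
        est.set_params(random_state=derive_seed(random_state, "wave", name))
        try:
            if holdout_estimates:
                estimates = _crossval_estimates(est, X, y, n_folds, random_state, name)
                est.fit(X, y)
            else:
                est.fit(X, y)
                estimates = est.predict(X)
        except Exception as exc:  # annotate failures with the wave
            raise type(exc)(f"wave {name!r}: {exc}") from exc
        r = _pearson(estimates, y)
        logger.info("wave %-22s width=%-3d r=%.3f epochs=%d", name, X.shape[1], r, est.n_iter_)
        waves.append(WaveResult(name, estimates, r, est))
    return WaveSet(waves)


def _crossval_estimates(est, X: pd.DataFrame, y: np.ndarray, n_folds: int, seed: int, name: str):
    from sklearn.model_selection import KFold

    out = np.empty(len(y))
    splitter = KFold(n_splits=n_folds, shuffle=True, random_state=derive_seed(seed, "cv", name))
    for fold, (tr, te) in enumerate(splitter.split(X)):
        m = clone(est)
        m.set_params(random_state=derive_seed(seed, "cvfit", name, fold))
        m.fit(X.iloc[tr], y[tr])
        out[te] = m.predict(X.iloc[te])
    return out
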