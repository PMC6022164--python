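"""Shallow neural regressors trained with Levenberg-Marquardt.

Two scikit-learn-style estimators:

* :class:`FeedforwardRegressor` — a two-layer network (tanh hidden layer,
  linear output) mapping the 18 per-video summary features to the three
  reference targets (HR, systolic, diastolic).  Default topology 18-10-3.
* :class:`NARXRegressor` — a nonlinear autoregressive network with exogenous
  inputs in series-parallel (open-loop) mode: each per-second prediction of
  the two targets (luminosity signal, HR) is regressed on the two most
  recent exogenous input rows and the two most recent *measured* targets.
  Default topology (2x9 + 2x2) = 22 -> 5 -> 2.

Both are trained by damped Gauss-Newton on the full Jacobian (the classic
Marquardt lambda schedule: x10 on a rejected step, /10 on an accepted one)
minimising mean squared error on [-1, 1]-normalized data, with
validation-based early stopping: training halts after 6 consecutive epochs
without a validation improvement (or at 1000 epochs) and the weights at the
best-validation epoch are kept.  Data are divided 70/15/15 at random; the
normalization settings are fitted on the training partition only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats as sstats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .errors import AlignmentError, InsufficientHistoryError
from .features import SymmetricMinMaxScaler, split_indices

__all__ = [
    "FeedforwardRegressor",
    "NARXRegressor",
    "TrainingReport",
    "StageMetrics",
    "evaluate_fit",
    "neuron_grid",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class StageMetrics:
    """Sample count, MSE and Pearson R for one training stage."""

    n: int
    mse: float
    r: float


@dataclass(frozen=True)
class TrainingReport:
    """Per-stage fit quality plus overall regression diagnostics.

    MSE and R are computed on the normalized [-1, 1] scale (the scale the
    optimizer sees); ``r_physical`` additionally reports overall R after
    denormalization to physical units.
    """

    stages: dict[str, StageMetrics]
    best_epoch: int
    n_epochs: int
    seed: int | None
    slope: float
    p_value: float
    r_physical: float | None = None

    def __getitem__(self, stage: str) -> StageMetrics:
        return self.stages[stage]


def _pooled_pearson(pred: np.ndarray, target: np.ndarray) -> float:
    """Pearson R pooling all output columns, as regression scatter plots do."""
    p, t = pred.ravel(), target.ravel()
    if p.std() == 0 or t.std() == 0:
        return float("nan")
    return float(np.corrcoef(p, t)[0, 1])


def evaluate_fit(
    predictions: np.ndarray,
    targets: np.ndarray,
    stage_labels: np.ndarray,
    best_epoch: int = 0,
    n_epochs: int = 0,
    seed: int | None = None,
    predictions_physical: np.ndarray | None = None,
    targets_physical: np.ndarray | None = None,
) -> TrainingReport:
    """Per-stage and overall MSE / Pearson R, plus overall slope and p-value.

    ``stage_labels`` assigns each row to 'train', 'validation' or 'test';
    an 'overall' stage pooling every row is always added.
    """
    predictions = np.atleast_2d(np.asarray(predictions, float))
    targets = np.atleast_2d(np.asarray(targets, float))
    if predictions.shape != targets.shape:
        raise AlignmentError(
            f"predictions {predictions.shape} vs targets {targets.shape}"
        )
    labels = np.asarray(stage_labels)
    stages: dict[str, StageMetrics] = {}
    for stage in ("train", "validation", "test"):
        mask = labels == stage
        if not mask.any():
            continue
        p, t = predictions[mask], targets[mask]
        stages[stage] = StageMetrics(
            n=int(mask.sum()),
            mse=float(np.mean((p - t) ** 2)),
            r=_pooled_pearson(p, t),
        )
    stages["overall"] = StageMetrics(
        n=len(predictions),
        mse=float(np.mean((predictions - targets) ** 2)),
        r=_pooled_pearson(predictions, targets),
    )
    if predictions.ravel().std() > 0:
        fit = sstats.linregress(targets.ravel(), predictions.ravel())
        slope, p_value = float(fit.slope), float(fit.pvalue)
    else:
        slope, p_value = float("nan"), float("nan")
    r_phys = None
    if predictions_physical is not None and targets_physical is not None:
        r_phys = _pooled_pearson(
            np.atleast_2d(predictions_physical), np.atleast_2d(targets_physical)
        )
    return TrainingReport(
        stages=stages,
        best_epoch=best_epoch,
        n_epochs=n_epochs,
        seed=seed,
        slope=slope,
        p_value=p_value,
        r_physical=r_phys,
    )


# ---------------------------------------------------------------------------
# Two-layer network core + Levenberg-Marquardt
# ---------------------------------------------------------------------------


class _TwoLayerNet:
    """tanh-hidden / linear-output network with analytic Jacobian."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int):
        self.n_in, self.n_hidden, self.n_out = n_in, n_hidden, n_out
        self.n_params = n_hidden * n_in + n_hidden + n_out * n_hidden + n_out

    def init_params(self, rng: np.random.Generator) -> np.ndarray:
        # small fan-in-scaled uniform start keeps the first LM steps stable
        w1 = rng.uniform(-1, 1, (self.n_hidden, self.n_in)) / np.sqrt(self.n_in)
        b1 = rng.uniform(-1, 1, self.n_hidden) / np.sqrt(self.n_in)
        w2 = rng.uniform(-1, 1, (self.n_out, self.n_hidden)) / np.sqrt(self.n_hidden)
        b2 = rng.uniform(-1, 1, self.n_out) / np.sqrt(self.n_hidden)
        return np.concatenate([w1.ravel(), b1, w2.ravel(), b2])

    def unpack(self, params: np.ndarray):
        h, i, o = self.n_hidden, self.n_in, self.n_out
        p = 0
        w1 = params[p : p + h * i].reshape(h, i); p += h * i
        b1 = params[p : p + h]; p += h
        w2 = params[p : p + o * h].reshape(o, h); p += o * h
        b2 = params[p : p + o]
        return w1, b1, w2, b2

    def forward(self, params: np.ndarray, X: np.ndarray) -> np.ndarray:
        w1, b1, w2, b2 = self.unpack(params)
        h = np.tanh(X @ w1.T + b1)
        return h @ w2.T + b2

    def forward_jacobian(self, params: np.ndarray, X: np.ndarray):
        """Outputs and d(output)/d(params), shape (n*n_out, n_params)."""
        w1, b1, w2, b2 = self.unpack(params)
        n = X.shape[0]
        z = X @ w1.T + b1
        h = np.tanh(z)                     # (n, H)
        out = h @ w2.T + b2                # (n, O)
        s = 1.0 - h * h                    # tanh'
        # d out[k] / d w1[j, i] = w2[k, j] * s[:, j] * X[:, i]
        j_w1 = np.einsum("kj,nj,ni->nkji", w2, s, X).reshape(
            n * self.n_out, self.n_hidden * self.n_in
        )
        j_b1 = np.einsum("kj,nj->nkj", w2, s).reshape(
            n * self.n_out, self.n_hidden
        )
        eye = np.eye(self.n_out)
        j_w2 = np.einsum("km,nj->nkmj", eye, h).reshape(
            n * self.n_out, self.n_out * self.n_hidden
        )
        j_b2 = np.tile(eye, (n, 1))
        return out, np.hstack([j_w1, j_b1, j_w2, j_b2])


def _train_lm(
    net: _TwoLayerNet,
    params: np.ndarray,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    max_epochs: int,
    patience: int,
    lambda_init: float,
    lambda_max: float = 1e10,
):
    """Damped Gauss-Newton with validation-based early stopping.

    Returns (best_params, best_epoch, n_epochs).  The returned weights are
    those at the epoch with minimum validation MSE.
    """
    lam = lambda_init
    train_mse = float(np.mean((net.forward(params, X_train) - y_train) ** 2))
    best_params = params.copy()
    best_val = float(np.mean((net.forward(params, X_val) - y_val) ** 2))
    best_epoch, fails = 0, 0
    epoch = 0
    for epoch in range(1, max_epochs + 1):
        out, J = net.forward_jacobian(params, X_train)
        r = (out - y_train).ravel()
        jtj = J.T @ J
        jtr = J.T @ r
        accepted = False
        while lam <= lambda_max:
            try:
                delta = np.linalg.solve(
                    jtj + lam * np.eye(net.n_params), -jtr
                )
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            cand = params + delta
            cand_mse = float(
                np.mean((net.forward(cand, X_train) - y_train) ** 2)
            )
            if cand_mse < train_mse:
                params, train_mse = cand, cand_mse
                lam = max(lam / 10.0, 1e-20)
                accepted = True
                break
            lam *= 10.0
        if not accepted:  # lambda exhausted: local minimum reached
            break
        val_mse = float(np.mean((net.forward(params, X_val) - y_val) ** 2))
        if val_mse < best_val - 1e-15:
            best_val, best_params, best_epoch = val_mse, params.copy(), epoch
            fails = 0
        else:
            fails += 1
            if fails >= patience:
                break
    return best_params, best_epoch, epoch


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


class FeedforwardRegressor(RegressorMixin, BaseEstimator):
    """Two-layer regression network (tanh hidden layer, linear output).

    Inputs and targets are normalized to [-1, 1] with settings fitted on the
    training partition; training uses Levenberg-Marquardt with validation
    early stopping on a random 70/15/15 division.

    Parameters
    ----------
    n_hidden : int, default=10
        Hidden-layer width.
    max_epochs : int, default=1000
        Hard cap on accepted LM steps.
    patience : int, default=6
        Consecutive validation failures tolerated before stopping.
    lambda_init : float, default=1e-3
        Initial Marquardt damping.
    random_state : int or None
        Seeds weight initialization and the data division.

    Attributes
    ----------
    coefs_ : tuple (W1, b1, W2, b2)
        Trained weights at the best-validation epoch.
    input_scaler_, target_scaler_ : SymmetricMinMaxScaler
        Recoverable normalization settings.
    report_ : TrainingReport
        Per-stage MSE / R computed on the normalized scale.
    """

    def __init__(
        self,
        n_hidden: int = 10,
        max_epochs: int = 1000,
        patience: int = 6,
        lambda_init: float = 1e-3,
        random_state: int | None = None,
    ):
        self.n_hidden = n_hidden
        self.max_epochs = max_epochs
        self.patience = patience
        self.lambda_init = lambda_init
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, multi_output=True, y_numeric=True, dtype=float)
        y = np.atleast_2d(y.T).T if y.ndim == 1 else y
        if len(X) < 30:
            raise ValueError(f"need >= 30 samples to train; got {len(X)}")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in inputs or targets")
        rng = np.random.default_rng(self.random_state)
        tr, va, te = split_indices(len(X), rng)

        self.input_scaler_ = SymmetricMinMaxScaler().fit(X[tr])
        self.target_scaler_ = SymmetricMinMaxScaler().fit(y[tr])
        Xn = self.input_scaler_.transform(X)
        yn = self.target_scaler_.transform(y)

        net = _TwoLayerNet(X.shape[1], self.n_hidden, y.shape[1])
        params0 = net.init_params(rng)
        params, best_epoch, n_epochs = _train_lm(
            net, params0, Xn[tr], yn[tr], Xn[va], yn[va],
            self.max_epochs, self.patience, self.lambda_init,
        )
        self._net = net
        self._params = params
        self.coefs_ = net.unpack(params)
        self.n_features_in_ = X.shape[1]
        self.n_outputs_ = y.shape[1]
        self.n_iter_ = n_epochs
        self.best_epoch_ = best_epoch

        labels = np.empty(len(X), dtype=object)
        labels[tr], labels[va], labels[te] = "train", "validation", "test"
        pred_n = net.forward(params, Xn)
        self.report_ = evaluate_fit(
            pred_n, yn, labels,
            best_epoch=best_epoch, n_epochs=n_epochs, seed=self.random_state,
            predictions_physical=self.target_scaler_.inverse_transform(pred_n),
            targets_physical=y,
        )
        return self

    def predict(self, X):
        """Denormalized predictions (physical units) for raw-unit inputs."""
        check_is_fitted(self, "_params")
        X = check_array(X, dtype=float)
        pred_n = self._net.forward(self._params, self.input_scaler_.transform(X))
        return self.target_scaler_.inverse_transform(pred_n)


class NARXRegressor(RegressorMixin, BaseEstimator):
    """Series-parallel NARX network for per-second target prediction.

    The regressor for time ``t`` concatenates the exogenous input rows at
    ``t-1 .. t-delays`` with the measured target rows at ``t-1 .. t-delays``
    (open loop: true past targets are fed back, during training and during
    prediction).  With 9 exogenous inputs, 2 targets and 2 delays the
    effective regressor width is 22.

    Parameters mirror :class:`FeedforwardRegressor` plus ``delays``.
    """

    def __init__(
        self,
        delays: int = 2,
        n_hidden: int = 5,
        max_epochs: int = 1000,
        patience: int = 6,
        lambda_init: float = 1e-3,
        random_state: int | None = None,
    ):
        self.delays = delays
        self.n_hidden = n_hidden
        self.max_epochs = max_epochs
        self.patience = patience
        self.lambda_init = lambda_init
        self.random_state = random_state

    def _regressor_matrix(self, Xn: np.ndarray, yn: np.ndarray):
        """Lagged design matrix for rows with full delay history."""
        d = self.delays
        n = len(Xn)
        blocks = [Xn[d - k : n - k] for k in range(1, d + 1)]
        blocks += [yn[d - k : n - k] for k in range(1, d + 1)]
        return np.hstack(blocks)

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = check_array(y, dtype=float, ensure_2d=False)
        y = y.reshape(-1, 1) if y.ndim == 1 else y
        if len(X) != len(y):
            raise AlignmentError(
                f"inputs have {len(X)} rows but targets {len(y)}"
            )
        if len(X) < 200:
            raise ValueError(f"need >= 200 time rows; got {len(X)}")
        rng = np.random.default_rng(self.random_state)

        # normalization fitted on the training rows of the lagged design
        n_eff = len(X) - self.delays
        tr, va, te = split_indices(n_eff, rng)
        # fit scalers on the raw rows feeding the training regressors
        self.input_scaler_ = SymmetricMinMaxScaler().fit(X)
        self.target_scaler_ = SymmetricMinMaxScaler().fit(y)
        Xn = self.input_scaler_.transform(X)
        yn = self.target_scaler_.transform(y)

        R = self._regressor_matrix(Xn, yn)
        T = yn[self.delays :]
        net = _TwoLayerNet(R.shape[1], self.n_hidden, T.shape[1])
        params0 = net.init_params(rng)
        params, best_epoch, n_epochs = _train_lm(
            net, params0, R[tr], T[tr], R[va], T[va],
            self.max_epochs, self.patience, self.lambda_init,
        )
        self._net = net
        self._params = params
        self.coefs_ = net.unpack(params)
        self.n_features_in_ = X.shape[1]
        self.n_outputs_ = T.shape[1]
        self.n_iter_ = n_epochs
        self.best_epoch_ = best_epoch

        labels = np.empty(n_eff, dtype=object)
        labels[tr], labels[va], labels[te] = "train", "validation", "test"
        pred_n = net.forward(params, R)
        self.report_ = evaluate_fit(
            pred_n, T, labels,
            best_epoch=best_epoch, n_epochs=n_epochs, seed=self.random_state,
            predictions_physical=self.target_scaler_.inverse_transform(pred_n),
            targets_physical=y[self.delays :],
        )
        return self

    def predict(self, X, y_history):
        """Open-loop one-step-ahead predictions in physical units.

        ``y_history`` holds the measured targets aligned with ``X``; the
        first prediction is emitted at row index ``delays`` (t = 2 s with
        the default two delays at 1 s cadence).
        """
        check_is_fitted(self, "_params")
        X = check_array(X, dtype=float)
        y_history = np.asarray(y_history, dtype=float)
        y_history = (
            y_history.reshape(-1, 1) if y_history.ndim == 1 else y_history
        )
        if len(y_history) < self.delays:
            raise InsufficientHistoryError(
                f"need >= {self.delays} rows of target history; "
                f"got {len(y_history)}"
            )
        if len(X) != len(y_history):
            raise AlignmentError(
                f"inputs have {len(X)} rows but history {len(y_history)}"
            )
        Xn = self.input_scaler_.transform(X)
        yn = self.target_scaler_.transform(y_history)
        R = self._regressor_matrix(Xn, yn)
        pred_n = self._net.forward(self._params, R)
        return self.target_scaler_.inverse_transform(pred_n)

    def prediction_times(self, n_rows: int, step_s: float = 1.0) -> np.ndarray:
        """Timestamps of the predictions for ``n_rows`` input rows."""
        return np.arange(self.delays, n_rows) * step_s


def neuron_grid(
    estimator_factory,
    X,
    y,
    sizes=(3, 5, 7, 10),
    random_state: int | None = None,
):
    """Manual neuron-trimming sweep: retrain at each hidden size.

    Returns ``{size: TrainingReport}``; model choice is left to the caller
    (the sweep is a diagnostic, not an automatic search).
    """
    reports = {}
    for size in sizes:
        est = estimator_factory(n_hidden=size, random_state=random_state)
        est.fit(X, y)
        reports[size] = est.report_
    return reports


# ---------------------------------------------------------------------------
# Model persistence (versioned JSON schema)
# ---------------------------------------------------------------------------

_SCHEMA_VERSION = 1


def save_model(model, path: str | Path) -> None:
    """Serialize a fitted estimator (architecture, weights, normalization
    settings, seed) to a versioned JSON file."""
    check_is_fitted(model, "_params")
    w1, b1, w2, b2 = model.coefs_
    doc = {
        "schema_version": _SCHEMA_VERSION,
        "kind": type(model).__name__,
        "params": model.get_params(),
        "weights": {
            "w1": w1.tolist(), "b1": b1.tolist(),
            "w2": w2.tolist(), "b2": b2.tolist(),
        },
        "input_scaler": model.input_scaler_.to_dict(),
        "target_scaler": model.target_scaler_.to_dict(),
        "n_features_in": int(model.n_features_in_),
        "n_outputs": int(model.n_outputs_),
        "best_epoch": int(model.best_epoch_),
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path):
    """Restore an estimator saved by :func:`save_model`."""
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != _SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema: {doc.get('schema_version')}")
    cls = {"FeedforwardRegressor": FeedforwardRegressor,
           "NARXRegressor": NARXRegressor}[doc["kind"]]
    model = cls(**doc["params"])
    w = doc["weights"]
    w1 = np.asarray(w["w1"], float)
    b1 = np.asarray(w["b1"], float)
    w2 = np.asarray(w["w2"], float)
    b2 = np.asarray(w["b2"], float)
    if doc["kind"] == "NARXRegressor":
        n_in_eff = w1.shape[1]
    else:
        n_in_eff = doc["n_features_in"]
    net = _TwoLayerNet(n_in_eff, w1.shape[0], w2.shape[0])
    model._net = net
    model._params = np.concatenate([w1.ravel(), b1, w2.ravel(), b2])
    model.coefs_ = (w1, b1, w2, b2)
    model.input_scaler_ = SymmetricMinMaxScaler.from_dict(doc["input_scaler"])
    model.target_scaler_ = SymmetricMinMaxScaler.from_dict(doc["target_scaler"])
    model.n_features_in_ = doc["n_features_in"]
    model.n_outputs_ = doc["n_outputs"]
    model.best_epoch_ = doc["best_epoch"]
    return model
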