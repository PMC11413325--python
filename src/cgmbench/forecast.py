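"""Forecaster families behind one fit/predict contract.

Three personalised, per-patient model families are benchmarked, each in a
univariate (glucose only) and a multivariate (glucose + carbohydrate +
bolus + activity) flavour at 30- and 60-minute horizons:

* classical time-series forecasting — ARIMA, or ARIMAX with the event and
  activity channels as exogenous regressors (this module);
* traditional machine learning — RBF-kernel support-vector regression on
  sliding windows (this module);
* a sequence-to-sequence LSTM (:mod:`cgmbench.nn`).

All forecasters emit :class:`ForecastSeries` aligned to the same
target-time grid for a given patient and horizon, so downstream metric
comparisons are paired by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVR
from statsmodels.tsa.arima.model import ARIMA

__all__ = [
    "ArimaOrder",
    "SvrParams",
    "ForecastSeries",
    "select_arima_order",
    "arma_rolling_forecast",
    "fit_predict_ctf",
    "grid_search_svr",
    "fit_predict_tml",
    "persistence_baseline",
]

STEP_MINUTES = 5


@dataclass(frozen=True)
class ArimaOrder:
    """ARIMA order (p, d, q); p and q searched, d from the stationarity gate."""

    p: int
    d: int
    q: int

    def __post_init__(self) -> None:
        if min(self.p, self.d, self.q) < 0:
            raise ValueError("orders must be non-negative")
        if self.d > 2:
            raise ValueError("differencing order capped at 2")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.p, self.d, self.q)


@dataclass(frozen=True)
class SvrParams:
    """RBF-SVR hyperparameters chosen by grid search."""

    gamma: float
    C: float
    epsilon: float


@dataclass
class ForecastSeries:
    """Model predictions aligned to reference test values at one horizon."""

    target_times: pd.DatetimeIndex
    predicted: np.ndarray
    reference: np.ndarray
    reference_imputed: np.ndarray
    horizon: int  # minutes
    model: str
    input_mode: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.target_times)
        if not (len(self.predicted) == len(self.reference)
                == len(self.reference_imputed) == n):
            raise ValueError("forecast fields must have equal length")

    def __len__(self) -> int:
        return len(self.predicted)


# ---------------------------------------------------------------------------
# classical track: ARIMA / ARIMAX


def _fit_arima(y: np.ndarray, order: tuple[int, int, int],
               exog: pd.DataFrame | None):
    trend = "c" if order[1] == 0 else "n"
    model = ARIMA(y, exog=exog, order=order, trend=trend)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit()


def select_arima_order(train: np.ndarray | pd.Series,
                       d: int,
                       search_max: int = 4,
                       exog: pd.DataFrame | None = None,
                       criterion: str = "aic") -> ArimaOrder:
    """Select (p, d, q) by information-criterion minimisation over a grid.

    Every (p, q) pair with p, q <= ``search_max`` is fitted and the pair
    minimising the criterion (AIC by default) wins; ties break toward
    smaller p + q, then smaller p.  ``search_max = 0`` returns (0, d, 0)
    without searching.
    """
    if search_max < 0:
        raise ValueError("search_max must be >= 0")
    if search_max == 0:
        return ArimaOrder(0, d, 0)
    y = np.asarray(train, dtype=float)
    best: tuple[float, int, int, int] | None = None
    failures: list[str] = []
    for p, q in product(range(search_max + 1), repeat=2):
        try:
            res = _fit_arima(y, (p, d, q), exog)
            score = getattr(res, criterion)
            if not np.isfinite(score):
                raise ValueError("non-finite criterion")
        except Exception as exc:  # noqa: BLE001 - collect and report
            failures.append(f"({p},{d},{q}): {exc}")
            continue
        key = (score, p + q, p)
        if best is None or key < (best[0], best[1], best[2]):
            best = (score, p + q, p, q)
    if best is None:
        raise RuntimeError(
            "all candidate ARIMA fits failed:\n" + "\n".join(failures))
    _, _, p, q = best
    return ArimaOrder(p, d, q)


def _params_by_name(res) -> tuple[float, np.ndarray, np.ndarray, dict]:
    """Split a fitted ARIMA parameter vector into (const, phi, theta, beta)."""
    const = 0.0
    phi, theta, beta = [], [], {}
    for name, value in zip(res.model.param_names, res.params):
        if name == "const":
            const = float(value)
        elif name.startswith("ar.L"):
            phi.append(float(value))
        elif name.startswith("ma.L"):
            theta.append(float(value))
        elif name == "sigma2":
            continue
        else:
            beta[name] = float(value)
    return const, np.asarray(phi), np.asarray(theta), beta


def _is_unstable(phi: np.ndarray, theta: np.ndarray,
                 tol: float = 1e-3) -> bool:
    """Explosive AR or non-invertible MA polynomial?

    AR roots solve 1 - phi_1 z - ... - phi_p z^p = 0 (stationary iff all
    |z| > 1); MA roots solve 1 + th_1 z + ... + th_q z^q = 0 likewise.
    """
    if phi.size:
        r = np.roots(np.r_[-phi[::-1], 1.0])
        if r.size and np.abs(r).min() <= 1 - tol:
            return True
    if theta.size:
        r = np.roots(np.r_[theta[::-1], 1.0])
        if r.size and np.abs(r).min() <= 1 - tol:
            return True
    return False


def arma_rolling_forecast(y: np.ndarray,
                          mu: np.ndarray,
                          phi: np.ndarray,
                          theta: np.ndarray,
                          d: int,
                          origins: np.ndarray,
                          horizon_steps: int) -> np.ndarray:
    """H-step-ahead forecasts of ``y`` from each origin via the ARIMA recursion.

    ``mu`` is the deterministic part (intercept plus exogenous regression)
    over the full series, including the forecast window — recorded future
    covariate values are deliberately used, since carbohydrate and bolus
    entries are known inputs at deployment time.  The stochastic part
    ``eta = y - mu`` is differenced ``d`` times to the zero-mean ARMA core
    ``w``; innovations come from the conditional-sum-of-squares recursion
    (eps and pre-sample w treated as zero), future innovations are zero,
    and forecasts are integrated back and re-centred.

    Returns one H-step-ahead prediction per origin: the forecast of
    ``y[o + horizon_steps]`` given data up to and including ``y[o]``.
    """
    y = np.asarray(y, dtype=float)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape)
    eta = y - mu
    w = np.diff(eta, n=d) if d else eta.copy()
    p, q = len(phi), len(theta)
    n_w = w.size

    eps = np.zeros(n_w)
    for t in range(n_w):
        acc = w[t]
        for i in range(1, p + 1):
            if t - i >= 0:
                acc -= phi[i - 1] * w[t - i]
        for j in range(1, q + 1):
            if t - j >= 0:
                acc -= theta[j - 1] * eps[t - j]
        eps[t] = acc

    H = int(horizon_steps)
    out = np.empty(len(origins))
    for k, o in enumerate(np.asarray(origins, dtype=int)):
        o_w = o - d  # index of the last known w
        hist = np.empty(o_w + 1 + H)
        hist[:o_w + 1] = w[:o_w + 1]
        for h in range(1, H + 1):
            t = o_w + h
            acc = 0.0
            for i in range(1, p + 1):
                if t - i >= 0:
                    acc += phi[i - 1] * hist[t - i]
            for j in range(1, q + 1):
                src = t - j
                if 0 <= src <= o_w:
                    acc += theta[j - 1] * eps[src]
            hist[t] = acc
        w_fc = hist[o_w + 1:]
        if d == 0:
            eta_fc = w_fc[-1]
        elif d == 1:
            eta_fc = eta[o] + w_fc.sum()
        else:  # d == 2
            level, slope = eta[o], eta[o] - eta[o - 1]
            for inc in w_fc:
                slope += inc
                level += slope
            eta_fc = level
        out[k] = mu[o + H] + eta_fc
    return out


def fit_predict_ctf(train: dict[str, pd.Series],
                    test: dict[str, pd.Series],
                    order: ArimaOrder,
                    horizon: int,
                    input_mode: str = "univariate",
                    test_imputed: pd.Series | None = None,
                    stride: int = 1) -> ForecastSeries:
    """Fit ARIMA/ARIMAX on the training span and roll H-step forecasts.

    For each test timestamp with sufficient history the model state is
    conditioned on all data up to the origin and the glucose value
    ``horizon`` minutes ahead is predicted.  Multivariate mode conditions
    on carbohydrate, bolus and activity as exogenous regressors, using
    their recorded values over the forecast window.  Explosive or
    non-invertible fits fall back to order (0, d, 0) with a warning.
    """
    H = horizon // STEP_MINUTES
    y_train = train["glucose"].to_numpy(dtype=float)
    y_test = test["glucose"].to_numpy(dtype=float)
    y_full = np.r_[y_train, y_test]
    exog_names = ("carb", "bolus", "activity")
    if input_mode == "multivariate":
        X_train = pd.DataFrame(
            {c: train[c].to_numpy(dtype=float) for c in exog_names})
        X_full = np.column_stack(
            [np.r_[train[c].to_numpy(dtype=float),
                   test[c].to_numpy(dtype=float)] for c in exog_names])
    elif input_mode == "univariate":
        X_train, X_full = None, None
    else:
        raise ValueError(f"unknown input_mode {input_mode!r}")

    res = _fit_arima(y_train, order.as_tuple(), X_train)
    const, phi, theta, beta = _params_by_name(res)
    used_order = order
    if _is_unstable(phi, theta):
        warnings.warn(
            f"unstable ARIMA fit at order {order.as_tuple()}; "
            f"falling back to (0, {order.d}, 0)", stacklevel=2)
        used_order = ArimaOrder(0, order.d, 0)
        res = _fit_arima(y_train, used_order.as_tuple(), X_train)
        const, phi, theta, beta = _params_by_name(res)

    mu = np.full(y_full.shape, const)
    if X_full is not None and beta:
        coefs = np.array([beta.get(c, beta.get(f"x{i + 1}", 0.0))
                          for i, c in enumerate(exog_names)])
        mu = mu + X_full @ coefs

    n_train = y_train.size
    # origins start H steps before the split so the target grid covers the
    # whole test span, matching the supervised-frame grids
    origins = np.arange(n_train - H, y_full.size - H, stride, dtype=int)
    preds = arma_rolling_forecast(y_full, mu, phi, theta, used_order.d,
                                  origins, H)
    target_idx = origins + H - n_train
    times = test["glucose"].index[target_idx]
    reference = y_test[target_idx]
    if test_imputed is not None:
        imput = test_imputed.to_numpy(dtype=bool)[target_idx]
    else:
        imput = np.zeros(target_idx.size, dtype=bool)
    return ForecastSeries(
        target_times=times, predicted=preds, reference=reference,
        reference_imputed=imput, horizon=horizon, model="ctf",
        input_mode=input_mode,
        meta={"order": used_order.as_tuple(), "requested": order.as_tuple()},
    )


# ---------------------------------------------------------------------------
# traditional machine-learning track: RBF-SVR on sliding windows


def _flatten(frame) -> np.ndarray:
    return frame.inputs.reshape(len(frame), -1)


class _SvrPipeline:
    """Min-max scaled single-output SVR predicting the final horizon step."""

    def __init__(self, params: SvrParams):
        self.params = params
        self.x_scaler = MinMaxScaler()
        self.y_scaler = MinMaxScaler()
        self.svr = SVR(kernel="rbf", gamma=params.gamma, C=params.C,
                       epsilon=params.epsilon)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_SvrPipeline":
        Xs = self.x_scaler.fit_transform(X)
        ys = self.y_scaler.fit_transform(y[:, None])[:, 0]
        self.svr.fit(Xs, ys)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        ps = self.svr.predict(self.x_scaler.transform(X))
        return self.y_scaler.inverse_transform(ps[:, None])[:, 0]


def grid_search_svr(frame,
                    gamma_space=(0.1, 1.0, 10.0, 100.0),
                    C_space=(0.001, 0.01, 0.1, 1.0),
                    epsilon_space=(0.01, 0.1, 1.0, 10.0),
                    validation_fraction: float = 0.2) -> SvrParams:
    """Pick (gamma, C, epsilon) minimising time-ordered validation RMSE.

    The final ``validation_fraction`` of the training frame (no
    shuffling) serves as the validation split; the regressor predicts the
    glucose value at the final horizon step.  Ties break toward smaller C,
    then smaller gamma.
    """
    if len(frame) == 0:
        raise ValueError("empty supervised frame")
    for space in (gamma_space, C_space, epsilon_space):
        if len(space) == 0:
            raise ValueError("empty hyperparameter space")
    X = _flatten(frame)
    y = frame.targets[:, -1]
    n_val = int(round(len(frame) * validation_fraction))
    if n_val < 1 or n_val >= len(frame):
        raise ValueError("validation split is empty or swallows all data")
    X_fit, y_fit = X[:-n_val], y[:-n_val]
    X_val, y_val = X[-n_val:], y[-n_val:]

    combos = list(product(gamma_space, C_space, epsilon_space))
    if len(combos) == 1:
        g, c, e = combos[0]
        return SvrParams(gamma=g, C=c, epsilon=e)
    best_key, best = None, None
    for g, c, e in combos:
        model = _SvrPipeline(SvrParams(g, c, e)).fit(X_fit, y_fit)
        rmse = float(np.sqrt(np.mean((model.predict(X_val) - y_val) ** 2)))
        key = (rmse, c, g, e)
        if best_key is None or key < best_key:
            best_key, best = key, SvrParams(gamma=g, C=c, epsilon=e)
    return best


def fit_predict_tml(frame_train, frame_test,
                    params: SvrParams) -> ForecastSeries:
    """Train the RBF-SVR on flattened windows and score the test frame.

    One single-output regressor predicts glucose at the final horizon step
    from the flattened (L*C)-length history vector; inputs and targets are
    min-max scaled on the training data and predictions inverse-
    transformed before scoring.
    """
    if (frame_train.history_length != frame_test.history_length
            or frame_train.horizon != frame_test.horizon
            or frame_train.channels != frame_test.channels):
        raise ValueError("train and test frames must share L, H and channels")
    model = _SvrPipeline(params).fit(_flatten(frame_train),
                                     frame_train.targets[:, -1])
    preds = model.predict(_flatten(frame_test))
    mode = "univariate" if len(frame_test.channels) == 1 else "multivariate"
    return ForecastSeries(
        target_times=frame_test.target_times,
        predicted=preds,
        reference=frame_test.targets[:, -1],
        reference_imputed=frame_test.target_imputed,
        horizon=frame_test.horizon * STEP_MINUTES,
        model="tml", input_mode=mode,
        meta={"params": params.__dict__},
    )


# ---------------------------------------------------------------------------
# baseline


def persistence_baseline(test_glucose: pd.Series,
                         horizon: int,
                         test_imputed: pd.Series | None = None,
                         history: pd.Series | None = None
                         ) -> ForecastSeries:
    """Naive yardstick: the prediction at t+H is the observation at t.

    When ``history`` (the tail of the training series) is given, the
    earliest test targets are predicted from it, so the baseline covers
    the same full test-span target grid as the model forecasters.
    """
    H = horizon // STEP_MINUTES
    if history is not None:
        full = pd.concat([history.iloc[-H:], test_glucose])
    else:
        full = test_glucose
    y = full.to_numpy(dtype=float)
    if y.size <= H:
        raise ValueError("series shorter than the horizon")
    n_skip = H - (len(full) - len(test_glucose))
    times = full.index[H:]
    reference = y[H:]
    predicted = y[:-H]
    if test_imputed is not None:
        imput = test_imputed.to_numpy(dtype=bool)[n_skip:]
    else:
        imput = np.zeros(reference.size, dtype=bool)
    return ForecastSeries(
        target_times=times, predicted=predicted, reference=reference,
        reference_imputed=imput, horizon=horizon,
        model="persistence", input_mode="univariate",
    )
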