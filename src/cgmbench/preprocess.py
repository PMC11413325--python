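"""Preprocessing chain: imputation, event zero-filling, activity alignment,
boundary trimming, stationarity-gated differencing, and supervised reframing.

The chain turns a raw :class:`~cgmbench.records.PatientRecord` into the two
shapes the forecasters consume: an aligned complete multichannel frame on
the 5-minute grid (for the classical ARIMA/ARIMAX track) and a sliding-
window :class:`SupervisedFrame` (for the machine-learning tracks).

Missing glucose/activity values are interpolated linearly in training
spans and extrapolated linearly in test spans — test-side fills use only
the last two observations before each gap, so the test pipeline stays
causal.  Unreported carbohydrate and bolus timestamps mean "no event" and
are zero-filled.  The 1-minute acceleration channel is downsampled by
keeping, for each glucose timestamp, the temporally nearest activity
sample and discarding the remainder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.tools.sm_exceptions import InterpolationWarning
from statsmodels.tsa.stattools import adfuller, kpss

from .records import PatientRecord

__all__ = [
    "StationarityVerdict",
    "SupervisedFrame",
    "impute_series",
    "zero_fill_events",
    "align_activity",
    "trim_boundaries",
    "determine_d",
    "reframe",
    "prepare_channels",
]

CHANNEL_ORDER = ("glucose", "carb", "bolus", "activity")


@dataclass(frozen=True)
class StationarityVerdict:
    """Outcome of the ADF/KPSS gate on an undifferenced series.

    ``is_stationary`` is true only when both tests agree at the configured
    level (ADF rejects a unit root, KPSS retains level stationarity);
    ``d`` is the smallest differencing order in {0, 1, 2} whose d-times
    differenced series passes KPSS.
    """

    adf_p: float
    kpss_p: float
    is_stationary: bool
    d: int


@dataclass
class SupervisedFrame:
    """Sliding-window supervised design for multi-step-ahead forecasting.

    ``inputs`` has shape ``(n, L, C)`` (history windows over the ordered
    channels), ``targets`` shape ``(n, H)`` (the next H glucose values),
    and ``target_times``/``target_imputed`` describe the final-step target
    of each pair.  Windows slide one step at a time; inputs end strictly
    before their targets begin.
    """

    history_length: int
    horizon: int
    channels: tuple[str, ...]
    inputs: np.ndarray
    targets: np.ndarray
    target_times: pd.DatetimeIndex
    target_imputed: np.ndarray

    def __post_init__(self) -> None:
        if len(self.inputs) != len(self.targets):
            raise ValueError("inputs and targets must pair one-to-one")

    def __len__(self) -> int:
        return len(self.inputs)


def impute_series(series: pd.Series, observed: pd.Series,
                  mode: str) -> tuple[pd.Series, pd.Series]:
    """Fill gaps linearly; return the complete series and an imputed flag.

    ``mode="train"`` interpolates each gap between its nearest observed
    neighbours (leading/trailing gaps fall back to nearest-value fill).
    ``mode="test"`` extrapolates forward from the last two observed points
    before each gap and never reads values after it, so downstream scoring
    can trust the fills to be causal.
    """
    if mode not in ("train", "test"):
        raise ValueError(f"mode must be 'train' or 'test', got {mode!r}")
    obs = observed.to_numpy(dtype=bool)
    if obs.sum() < 2:
        raise ValueError("need at least 2 observed points to impute")
    values = series.to_numpy(dtype=float).copy()
    n = values.size
    idx_obs = np.flatnonzero(obs)
    t = series.index.view("int64").astype(float)

    if mode == "train":
        filled = np.interp(t, t[idx_obs], values[idx_obs])
        filled[idx_obs] = values[idx_obs]
    else:
        filled = values.copy()
        for i in range(n):
            if obs[i]:
                continue
            prev = idx_obs[idx_obs < i]
            if prev.size >= 2:
                i1, i2 = prev[-2], prev[-1]
                slope = (values[i2] - values[i1]) / (t[i2] - t[i1])
                filled[i] = values[i2] + slope * (t[i] - t[i2])
            elif prev.size == 1:
                filled[i] = values[prev[-1]]
            else:  # gap before any observation: backfill from first point
                filled[i] = values[idx_obs[0]]
    imputed = pd.Series(~obs, index=series.index, name="imputed")
    return pd.Series(filled, index=series.index, name=series.name), imputed


def zero_fill_events(events: pd.DataFrame,
                     grid: pd.DatetimeIndex) -> pd.Series:
    """Bin an event log onto a regular grid; unreported timestamps are zero.

    Each event goes to its nearest grid point (ties break to the earlier
    point); simultaneous events in one bin are summed, conserving total
    grams/units.
    """
    out = np.zeros(len(grid))
    if len(events):
        gt = grid.view("int64")
        step = gt[1] - gt[0] if len(gt) > 1 else 1
        for ts, value in zip(events["ts"], events["value"]):
            tns = pd.Timestamp(ts).value
            # nearest grid point; exact half-step ties go to the earlier one
            lo = int(np.floor((tns - gt[0]) / step))
            if lo < 0:
                pos = 0
            elif lo >= len(gt) - 1:
                pos = len(gt) - 1
            else:
                d_lo = tns - gt[lo]
                d_hi = gt[lo + 1] - tns
                pos = lo if d_lo <= d_hi else lo + 1
            out[pos] += float(value)
    return pd.Series(out, index=grid, name="events")


def align_activity(activity: pd.Series,
                   glucose_grid: pd.DatetimeIndex) -> pd.Series:
    """Bring the activity channel onto the glucose grid.

    A 1-minute series is downsampled by keeping the temporally nearest
    sample for each glucose timestamp and discarding the remainder; a
    series already on the 5-minute grid is only aligned.  Ties between two
    equally near samples go to the earlier one.
    """
    if len(activity) == 0:
        raise ValueError("activity series is empty")
    at = activity.index.view("int64").astype(np.int64)
    gt = glucose_grid.view("int64").astype(np.int64)
    if at[-1] < gt[0] or at[0] > gt[-1]:
        raise ValueError("activity and glucose spans do not overlap")
    pos = np.searchsorted(at, gt)
    pos = np.clip(pos, 1, len(at) - 1)
    left, right = pos - 1, pos
    d_left = np.abs(gt - at[left])
    d_right = np.abs(at[right] - gt)
    choose_left = d_left <= d_right  # tie -> earlier sample
    nearest = np.where(choose_left, left, right)
    # grid points before the first / after the last sample clamp to ends
    nearest[gt <= at[0]] = 0
    nearest[gt >= at[-1]] = len(at) - 1
    return pd.Series(activity.to_numpy()[nearest], index=glucose_grid,
                     name="activity")


def trim_boundaries(channels: dict[str, pd.Series]) -> dict[str, pd.Series]:
    """Restrict every channel to the intersection of their time spans."""
    if not channels:
        raise ValueError("no channels to trim")
    start = max(s.index[0] for s in channels.values())
    end = min(s.index[-1] for s in channels.values())
    if start > end:
        raise ValueError("channel spans have empty intersection")
    return {name: s.loc[(s.index >= start) & (s.index <= end)]
            for name, s in channels.items()}


def determine_d(series: pd.Series | np.ndarray,
                alpha: float = 0.05,
                max_d: int = 2) -> StationarityVerdict:
    """Choose the integrated-differencing order via the ADF/KPSS gate.

    Runs both tests on the undifferenced series and records their
    p-values; ``d`` is the smallest order in {0..max_d} whose d-times
    differenced series passes the KPSS level-stationarity test at
    ``alpha`` (differencing is applied where KPSS indicates
    non-stationarity).  KPSS p-values outside the tabulated range are
    clipped to the table bounds, the usual convention.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 20:
        raise ValueError("series too short for stationarity testing")
    if np.ptp(x) == 0:
        raise ValueError("constant series: stationarity tests undefined")

    def kpss_p(values: np.ndarray) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", InterpolationWarning)
            return float(kpss(values, regression="c", nlags="auto")[1])

    adf_p = float(adfuller(x, autolag="AIC")[1])
    kpss_p0 = kpss_p(x)
    is_stationary = adf_p < alpha and kpss_p0 >= alpha

    d = None
    diffed = x
    for order in range(max_d + 1):
        if np.ptp(diffed) == 0:  # differencing removed all variation
            d = order
            break
        if kpss_p(diffed) >= alpha:
            d = order
            break
        diffed = np.diff(diffed)
    if d is None:
        d = max_d
    return StationarityVerdict(adf_p=adf_p, kpss_p=kpss_p0,
                               is_stationary=is_stationary, d=d)


def reframe(channels: dict[str, pd.Series],
            history_length: int,
            horizon: int,
            mode: str = "univariate",
            target_imputed: pd.Series | None = None) -> SupervisedFrame:
    """Reframe forecasting as supervised learning with sliding windows.

    Univariate mode uses glucose only; multivariate mode stacks glucose,
    carb, bolus and activity in that fixed order.  For a series of length
    N the frame holds ``N - L - H + 1`` input/target pairs.
    """
    if mode not in ("univariate", "multivariate"):
        raise ValueError(f"unknown mode {mode!r}")
    names = ("glucose",) if mode == "univariate" else CHANNEL_ORDER
    missing = [c for c in names if c not in channels]
    if missing:
        raise ValueError(f"missing channels: {missing}")
    glucose = channels["glucose"]
    n = len(glucose)
    L, H = int(history_length), int(horizon)
    if L <= 0 or H <= 0:
        raise ValueError("history_length and horizon must be positive")
    n_pairs = n - L - H + 1
    if n_pairs <= 0:
        raise ValueError(
            f"series of length {n} too short for L={L}, H={H}")

    mat = np.column_stack([channels[c].to_numpy(dtype=float) for c in names])
    idx_in = np.arange(L)[None, :] + np.arange(n_pairs)[:, None]
    inputs = mat[idx_in]  # (n_pairs, L, C)
    g = glucose.to_numpy(dtype=float)
    idx_tgt = np.arange(H)[None, :] + (np.arange(n_pairs) + L)[:, None]
    targets = g[idx_tgt]
    final = idx_tgt[:, -1]
    times = glucose.index[final]
    if target_imputed is not None:
        imput = target_imputed.to_numpy(dtype=bool)[final]
    else:
        imput = np.zeros(n_pairs, dtype=bool)
    return SupervisedFrame(history_length=L, horizon=H, channels=names,
                           inputs=inputs, targets=targets,
                           target_times=times, target_imputed=imput)


def reframe_test(train_channels: dict[str, pd.Series],
                 test_channels: dict[str, pd.Series],
                 history_length: int,
                 horizon: int,
                 mode: str = "univariate",
                 test_imputed: pd.Series | None = None) -> SupervisedFrame:
    """Supervised test frame whose targets cover the *entire* test span.

    History windows for the earliest test targets reach back into the
    training span (their inputs are past observations either way), so all
    forecasters and the persistence baseline share one target-time grid
    and metric comparisons are paired by construction.
    """
    L, H = int(history_length), int(horizon)
    tail = {name: pd.concat([s.iloc[-(L + H - 1):], test_channels[name]])
            for name, s in train_channels.items()}
    imputed = None
    if test_imputed is not None:
        pad = pd.Series(False, index=tail["glucose"].index[:L + H - 1])
        imputed = pd.concat([pad, test_imputed.astype(bool)])
    return reframe(tail, L, H, mode, target_imputed=imputed)


def prepare_channels(record: PatientRecord,
                     mode: str) -> tuple[dict[str, pd.Series], pd.Series]:
    """Run the imputation/zero-fill/alignment/trim chain on one record view.

    ``mode`` is ``"train"`` or ``"test"`` and controls the imputation rule.
    Returns the aligned complete channel dict on the glucose grid plus the
    glucose imputed-flag series (used downstream to mask scoring).
    """
    glucose, imputed = impute_series(record.glucose, record.glucose_observed,
                                     mode=mode)
    grid = glucose.index
    carb = zero_fill_events(record.carb, grid)
    bolus = zero_fill_events(record.bolus, grid)
    activity = align_activity(record.activity, grid)
    channels = trim_boundaries({
        "glucose": glucose, "carb": carb, "bolus": bolus,
        "activity": activity,
    })
    imputed = imputed.loc[channels["glucose"].index]
    return channels, imputed
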