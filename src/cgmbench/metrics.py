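"""Regression and clinical evaluation metrics for glucose forecasts.

Two regression metrics score every forecast over its N evaluated pairs:

    RMSE = sqrt( sum_i (y_i - yhat_i)^2 / N )
    MAE  =       sum_i |y_i - yhat_i|   / N

and two clinical metrics summarise how errors matter to a patient: the
Matthews correlation coefficient over adverse-versus-normoglycaemic event
classification (hypo below 70 mg/dL, hyper above 180 mg/dL by default),
and the surveillance error — the mean of a clinician-derived risk surface
over (reference, predicted) pairs, interpolated bilinearly between integer
grid nodes on [0, 600] x [0, 600] mg/dL.

Pairs whose reference value was imputed (test-side extrapolation fill) are
excluded from all metrics by default; ``include_imputed=True`` restores
them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forecast import ForecastSeries

__all__ = [
    "MetricRow",
    "SegGrid",
    "rmse",
    "mae",
    "classify_glycaemic_state",
    "mcc_events",
    "seg_risk",
    "surveillance_error",
    "synthetic_seg_grid",
    "score_forecast",
    "plot_seg",
]

HYPO_THRESHOLD = 70.0
HYPER_THRESHOLD = 180.0
SEG_MAX = 600


@dataclass(frozen=True)
class MetricRow:
    """One benchmark cell: (patient, model, input mode, horizon) scores."""

    patient_id: str
    model: str
    input_mode: str
    horizon: int
    rmse: float
    mae: float
    mcc: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.rmse < self.mae - 1e-9:
            raise ValueError("RMSE below MAE violates the power-mean "
                             "inequality")
        if not -1 - 1e-9 <= self.mcc <= 1 + 1e-9:
            raise ValueError("MCC outside [-1, 1]")
        if self.se < 0:
            raise ValueError("surveillance error must be non-negative")


@dataclass(frozen=True)
class SegGrid:
    """Risk lookup at integer (reference, predicted) nodes on [0, 600]^2.

    ``risk[r, p]`` is the clinical risk of predicting ``p`` mg/dL when the
    reference is ``r`` mg/dL.  Validated at construction: finite,
    non-negative, zero on the diagonal, and within each reference row
    unimodal with its minimum at the diagonal.
    """

    risk: np.ndarray
    provenance: str

    def __post_init__(self) -> None:
        r = self.risk
        if r.shape != (SEG_MAX + 1, SEG_MAX + 1):
            raise ValueError("risk grid must be 601x601")
        if not np.isfinite(r).all() or (r < 0).any():
            raise ValueError("risk values must be finite and non-negative")
        diag = np.diag(r)
        if not np.allclose(diag, 0.0):
            raise ValueError("risk must vanish on the diagonal")
        # row-wise unimodality: non-increasing left of the diagonal,
        # non-decreasing right of it
        for i in (0, SEG_MAX // 2, SEG_MAX):
            row = r[i]
            if not (np.diff(row[: i + 1]) <= 1e-9).all():
                raise ValueError(f"row {i} not non-increasing left of "
                                 "diagonal")
            if not (np.diff(row[i:]) >= -1e-9).all():
                raise ValueError(f"row {i} not non-decreasing right of "
                                 "diagonal")


def _risk_coordinate(x: np.ndarray) -> np.ndarray:
    """Monotone clinical-severity coordinate of a glucose value.

    Logarithmic, so equal *relative* glucose errors score equally and the
    hypoglycaemic range (where small absolute errors are dangerous) is
    stretched relative to the hyperglycaemic range.
    """
    return np.log(np.asarray(x, dtype=float) + 20.0)


def synthetic_seg_grid() -> SegGrid:
    """Construct a synthetic stand-in surveillance-risk surface.

    This is *not* the published consensus surveillance error grid: that
    lookup table is distributed with the original publication's software
    and is not bundled here.  The stand-in reproduces its qualitative
    structure — risk 0 on the diagonal, smooth growth with clinically
    scaled disagreement, a 0-4 range, and harsher penalties for missing
    hypoglycaemia — so every metric identity and pipeline behaviour is
    exercised faithfully.  Absolute SE values are therefore comparable
    within this package only.
    """
    g = np.arange(SEG_MAX + 1, dtype=float)
    coord = _risk_coordinate(g)
    diff = np.abs(coord[:, None] - coord[None, :])
    # severity weight grows when the *reference* is out of the safe range
    severity = 1.0 + 1.5 * np.exp(-g / 60.0) + 0.3 * np.clip(
        (g - HYPER_THRESHOLD) / 200.0, 0.0, None)
    risk = np.minimum(4.0, 2.2 * severity[:, None] * diff)
    np.fill_diagonal(risk, 0.0)
    return SegGrid(risk=risk, provenance="synthetic stand-in surface "
                   "(cgmbench.metrics.synthetic_seg_grid)")


def _scored(forecast: ForecastSeries,
            include_imputed: bool) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(forecast.reference, dtype=float)
    pred = np.asarray(forecast.predicted, dtype=float)
    if not include_imputed:
        keep = ~np.asarray(forecast.reference_imputed, dtype=bool)
        ref, pred = ref[keep], pred[keep]
    if ref.size == 0:
        raise ValueError("no scored pairs (all references imputed?)")
    return ref, pred


def rmse(forecast: ForecastSeries, include_imputed: bool = False) -> float:
    """Root mean square error over scored pairs, mg/dL."""
    ref, pred = _scored(forecast, include_imputed)
    return float(np.sqrt(np.mean((ref - pred) ** 2)))


def mae(forecast: ForecastSeries, include_imputed: bool = False) -> float:
    """Mean absolute error over scored pairs, mg/dL."""
    ref, pred = _scored(forecast, include_imputed)
    return float(np.mean(np.abs(ref - pred)))


def classify_glycaemic_state(value, hypo_threshold: float = HYPO_THRESHOLD,
                             hyper_threshold: float = HYPER_THRESHOLD):
    """True for adverse (hypo- or hyperglycaemic) states, False for normo.

    Strict inequalities: the boundary values themselves count as
    normoglycaemic.
    """
    if hypo_threshold >= hyper_threshold:
        raise ValueError("hypo threshold must lie below hyper threshold")
    v = np.asarray(value, dtype=float)
    out = (v < hypo_threshold) | (v > hyper_threshold)
    return bool(out) if np.isscalar(value) else out


def mcc_events(forecast: ForecastSeries,
               hypo_threshold: float = HYPO_THRESHOLD,
               hyper_threshold: float = HYPER_THRESHOLD,
               include_imputed: bool = False) -> float:
    """Matthews correlation of adverse-event detection, per timestep.

    Positives are adverse states.  Any zero factor in the denominator
    yields MCC = 0, the standard convention.
    """
    ref, pred = _scored(forecast, include_imputed)
    a_ref = classify_glycaemic_state(ref, hypo_threshold, hyper_threshold)
    a_pred = classify_glycaemic_state(pred, hypo_threshold, hyper_threshold)
    tp = float(np.sum(a_ref & a_pred))
    tn = float(np.sum(~a_ref & ~a_pred))
    fp = float(np.sum(~a_ref & a_pred))
    fn = float(np.sum(a_ref & ~a_pred))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def seg_risk(reference, predicted, grid: SegGrid):
    """Bilinearly interpolated risk of (reference, predicted) pairs.

    Inputs are clamped to [0, 600] mg/dL; the risk is interpolated among
    the four surrounding integer nodes, so queries at exact nodes return
    the node value and cell centres return the mean of the four corners.
    """
    ref = np.clip(np.asarray(reference, dtype=float), 0, SEG_MAX)
    pred = np.clip(np.asarray(predicted, dtype=float), 0, SEG_MAX)
    scalar = ref.ndim == 0
    ref, pred = np.atleast_1d(ref), np.atleast_1d(pred)
    r0 = np.clip(np.floor(ref).astype(int), 0, SEG_MAX - 1)
    p0 = np.clip(np.floor(pred).astype(int), 0, SEG_MAX - 1)
    fr, fp = ref - r0, pred - p0
    z = grid.risk
    val = (z[r0, p0] * (1 - fr) * (1 - fp)
           + z[r0 + 1, p0] * fr * (1 - fp)
           + z[r0, p0 + 1] * (1 - fr) * fp
           + z[r0 + 1, p0 + 1] * fr * fp)
    return float(val[0]) if scalar else val


def surveillance_error(forecast: ForecastSeries, grid: SegGrid,
                       include_imputed: bool = False) -> float:
    """Mean interpolated surveillance risk over scored pairs."""
    ref, pred = _scored(forecast, include_imputed)
    return float(np.mean(seg_risk(ref, pred, grid)))


def score_forecast(forecast: ForecastSeries, grid: SegGrid,
                   patient_id: str,
                   hypo_threshold: float = HYPO_THRESHOLD,
                   hyper_threshold: float = HYPER_THRESHOLD,
                   include_imputed: bool = False) -> MetricRow:
    """Compute all four metrics for one forecast."""
    ref, _ = _scored(forecast, include_imputed)
    return MetricRow(
        patient_id=patient_id,
        model=forecast.model,
        input_mode=forecast.input_mode,
        horizon=forecast.horizon,
        rmse=rmse(forecast, include_imputed),
        mae=mae(forecast, include_imputed),
        mcc=mcc_events(forecast, hypo_threshold, hyper_threshold,
                       include_imputed),
        se=surveillance_error(forecast, grid, include_imputed),
        n=int(ref.size),
    )


def plot_seg(forecast: ForecastSeries, grid: SegGrid, path,
             include_imputed: bool = False):
    """Colour-coded surveillance-grid scatter of (reference, predicted).

    Writes an image file; layout is deterministic given the forecast.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ref, pred = _scored(forecast, include_imputed)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(grid.risk.T, origin="lower", extent=(0, SEG_MAX, 0,
                                                        SEG_MAX),
                   cmap="RdYlGn_r", vmin=0, vmax=4, aspect="equal")
    ax.scatter(ref, pred, s=6, c="black", alpha=0.6, linewidths=0)
    ax.plot([0, SEG_MAX], [0, SEG_MAX], color="white", lw=0.8, ls="--")
    ax.set_xlabel("reference glucose (mg/dL)")
    ax.set_ylabel("predicted glucose (mg/dL)")
    ax.set_title(f"{forecast.model} / {forecast.input_mode} / "
                 f"{forecast.horizon} min")
    fig.colorbar(im, ax=ax, label="risk")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
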