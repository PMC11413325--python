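"""Core data containers for per-patient CGM records.

A :class:`PatientRecord` carries the four channels used throughout the
benchmark — CGM glucose on a regular 5-minute grid, timestamped carbohydrate
and bolus-insulin event logs, and one physical-activity channel (heart rate
at 5-minute resolution or acceleration magnitude at 1-minute resolution) —
together with the train/test split point.  All interval conventions are
half-open ``[start, end)``: the split boundary itself belongs to the test
side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GLUCOSE_MIN = 40.0
GLUCOSE_MAX = 400.0

HEART_RATE = "heart_rate_5min"
ACCEL_MAGNITUDE = "accel_magnitude_1min"


class ConfigurationError(ValueError):
    """Raised for invalid simulation or benchmark configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Generative settings for one synthetic T1DM cohort.

    Defaults mirror the structure of the real study records this package
    emulates: roughly eight weeks of data per patient sampled every five
    minutes, with the final ten days held out for testing, a handful of
    meals per day each covered by a bolus, and occasional sensor dropouts.

    Parameters
    ----------
    n_patients
        Cohort size (the real cohorts have six contributors each).
    duration_days, test_days
        Total record span and the length of the held-out tail.
    sample_interval
        Glucose grid spacing in minutes; must divide 60.
    basal_glucose
        Mean-reversion target of the glucose process, mg/dL.
    meal_rate
        Expected meals per day (daytime Poisson process).
    carb_size_distribution
        ``(mean, sd)`` of per-meal carbohydrate, grams.
    carb_to_bolus_ratio
        Grams of carbohydrate covered by one unit of insulin.
    meal_absorption_peak, insulin_action_peak
        Lag, in minutes, at which the meal / insulin impulse responses peak.
    activity_mode
        ``"heart_rate_5min"`` (bpm, on the glucose grid) or
        ``"accel_magnitude_1min"`` (unitless, 1-minute grid).
    gap_rate, gap_length_distribution
        Sensor-gap arrival rate (gaps/day) and ``(mean, sd)`` gap length in
        minutes.
    noise_sd
        Per-step Gaussian innovation, mg/dL.
    mean_reversion_rate
        Per-step pull toward ``basal_glucose`` (fraction in (0, 1)).
    """

    n_patients: int = 6
    duration_days: int = 56
    test_days: int = 10
    sample_interval: int = 5
    basal_glucose: float = 120.0
    meal_rate: float = 3.0
    carb_size_distribution: tuple[float, float] = (50.0, 15.0)
    carb_to_bolus_ratio: float = 10.0
    meal_absorption_peak: float = 60.0
    insulin_action_peak: float = 75.0
    activity_mode: str = HEART_RATE
    gap_rate: float = 1.0
    gap_length_distribution: tuple[float, float] = (30.0, 15.0)
    noise_sd: float = 5.0
    mean_reversion_rate: float = 0.035
    seed: int = 0
    # mg/dL moved per gram of carbohydrate / per unit of insulin, summed
    # over the whole impulse response
    carb_gain: float = 4.0
    insulin_drop: float = 32.0
    activity_gain: float = 0.6

    def __post_init__(self) -> None:
        if self.duration_days <= self.test_days or self.test_days < 0:
            raise ConfigurationError(
                "need duration_days > test_days >= 0, got "
                f"{self.duration_days} and {self.test_days}"
            )
        if self.sample_interval <= 0 or 60 % self.sample_interval != 0:
            raise ConfigurationError("sample_interval must divide 60")
        if self.meal_rate < 0 or self.gap_rate < 0:
            raise ConfigurationError("rates must be non-negative")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if not 0 < self.mean_reversion_rate < 1:
            raise ConfigurationError("mean_reversion_rate must lie in (0, 1)")
        if self.carb_to_bolus_ratio <= 0:
            raise ConfigurationError("carb_to_bolus_ratio must be positive")
        if self.activity_mode not in (HEART_RATE, ACCEL_MAGNITUDE):
            raise ConfigurationError(
                f"unknown activity_mode {self.activity_mode!r}"
            )


@dataclass
class PatientRecord:
    """One patient's aligned multichannel record.

    Attributes
    ----------
    glucose
        mg/dL on a strictly increasing regular grid (DatetimeIndex).
    glucose_observed
        Boolean mask aligned to ``glucose``; ``False`` marks sensor gaps.
    carb, bolus
        Event logs: DataFrames with columns ``ts`` and ``value`` (grams /
        insulin units).
    activity
        Heart rate on the glucose grid, or acceleration magnitude on a
        1-minute grid, depending on ``activity_mode``.
    split_point
        First timestamp of the test span (test side owns the boundary).
    """

    patient_id: str
    cohort: str
    glucose: pd.Series
    glucose_observed: pd.Series
    carb: pd.DataFrame
    bolus: pd.DataFrame
    activity: pd.Series
    activity_mode: str
    split_point: pd.Timestamp
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.glucose.index
        if len(idx) > 1:
            deltas = np.diff(idx.view("int64"))
            if not (deltas > 0).all() or len(set(deltas)) != 1:
                raise ValueError("glucose timestamps must form a regular, "
                                 "strictly increasing grid")
        if not self.glucose.index.equals(self.glucose_observed.index):
            raise ValueError("glucose and observed mask must share an index")

    @property
    def sample_interval(self) -> pd.Timedelta:
        return pd.Timedelta(self.glucose.index[1] - self.glucose.index[0])

    @property
    def missing_fraction(self) -> float:
        """Fraction of glucose grid points flagged missing."""
        return float((~self.glucose_observed).mean())

    def copy(self) -> "PatientRecord":
        return PatientRecord(
            patient_id=self.patient_id,
            cohort=self.cohort,
            glucose=self.glucose.copy(),
            glucose_observed=self.glucose_observed.copy(),
            carb=self.carb.copy(),
            bolus=self.bolus.copy(),
            activity=self.activity.copy(),
            activity_mode=self.activity_mode,
            split_point=self.split_point,
            meta=dict(self.meta),
        )

    def equals(self, other: "PatientRecord") -> bool:
        return (
            self.patient_id == other.patient_id
            and self.cohort == other.cohort
            and self.glucose.equals(other.glucose)
            and self.glucose_observed.equals(other.glucose_observed)
            and self.carb.reset_index(drop=True).equals(
                other.carb.reset_index(drop=True))
            and self.bolus.reset_index(drop=True).equals(
                other.bolus.reset_index(drop=True))
            and self.activity.equals(other.activity)
            and self.split_point == other.split_point
        )


def _slice_events(events: pd.DataFrame, start, end) -> pd.DataFrame:
    if len(events) == 0:
        return events.copy()
    mask = (events["ts"] >= start) & (events["ts"] < end)
    return events.loc[mask].reset_index(drop=True)


def split_train_test(
    record: PatientRecord, test_days: float
) -> tuple[PatientRecord, PatientRecord]:
    """Split a record into train and test views at ``test_days`` before its end.

    The boundary is half-open: a sample exactly at the split point belongs
    to the test view.  ``test_days = 0`` yields an empty test view.
    """
    idx = record.glucose.index
    span = idx[-1] - idx[0] + record.sample_interval
    cutoff = pd.Timedelta(days=test_days)
    if cutoff > span:
        raise ValueError(
            f"record spans {span}, shorter than requested test window {cutoff}"
        )
    end = idx[-1] + record.sample_interval
    split = end - cutoff

    def view(start, stop, tag):
        gmask = (idx >= start) & (idx < stop)
        if record.activity_mode == ACCEL_MAGNITUDE:
            aidx = record.activity.index
            amask = (aidx >= start) & (aidx < stop)
            activity = record.activity.loc[amask]
        else:
            activity = record.activity.loc[gmask]
        return PatientRecord(
            patient_id=record.patient_id,
            cohort=record.cohort,
            glucose=record.glucose.loc[gmask],
            glucose_observed=record.glucose_observed.loc[gmask],
            carb=_slice_events(record.carb, start, stop),
            bolus=_slice_events(record.bolus, start, stop),
            activity=activity,
            activity_mode=record.activity_mode,
            split_point=record.split_point,
            meta={**record.meta, "partition": tag},
        )

    return view(idx[0], split, "train"), view(split, end, "test")
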