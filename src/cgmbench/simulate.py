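"""Synthetic T1DM cohort generator.

The generator produces patient records with the statistical structure of
the real study cohorts — an ~8-week 5-minute CGM series with the last days
held out for testing, daytime meals each covered by a bolus, one activity
channel, and sensor gaps — without claiming physiological fidelity.  Its
purpose is to give every downstream stage (preprocessing, the three
forecaster families, metrics, statistics) inputs in which the carbohydrate,
insulin and activity channels genuinely carry information about future
glucose, so multivariate forecasters have signal to find.

Glucose follows a discrete-time mean-reverting impulse-response model on
the 5-minute grid:

    G[t+1] = G[t] + k * (G_basal - G[t])
             + sum_meals   c_m * f_meal(t - t_m)
             - sum_boluses u_b * f_ins(t - t_b)
             - a * activity_effect[t] + eps[t]

with ``f_meal`` and ``f_ins`` non-negative unimodal kernels peaking at the
configured absorption/action lags, ``eps`` zero-mean Gaussian, and the
result clamped to the sensor range [40, 400] mg/dL.  Everything is
deterministic given ``(seed, patient_index)``; patient substreams are
decoupled as ``seed + patient_index``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .records import (
    ACCEL_MAGNITUDE,
    GLUCOSE_MAX,
    GLUCOSE_MIN,
    HEART_RATE,
    ConfigurationError,
    PatientRecord,
    SimulationConfig,
    split_train_test,
)

__all__ = [
    "impulse_kernel",
    "simulate_patient",
    "inject_gaps",
    "simulate_cohort",
    "split_train_test",
]

_EPOCH = pd.Timestamp("2024-01-01 00:00:00")
_KERNEL_SPAN_MIN = 480.0  # truncate impulse responses at 8 h


def impulse_kernel(peak_minutes: float, step_minutes: float) -> np.ndarray:
    """Discrete non-negative unimodal kernel peaking at ``peak_minutes``.

    Gamma-type shape ``w(tau) ~ tau * exp(-tau / peak)`` sampled on the
    grid and normalised to sum to one, so a meal of ``c`` grams moves
    glucose by ``c * carb_gain`` mg/dL in total.
    """
    if peak_minutes <= 0 or step_minutes <= 0:
        raise ConfigurationError("kernel peak and step must be positive")
    tau = np.arange(step_minutes, _KERNEL_SPAN_MIN + step_minutes,
                    step_minutes)
    w = tau * np.exp(-tau / peak_minutes)
    return w / w.sum()


def _daytime_event_times(rng: np.random.Generator, n_days: int,
                         rate_per_day: float) -> np.ndarray:
    """Poisson daily counts with event minutes uniform in 06:00-22:00."""
    times = []
    for day in range(n_days):
        for _ in range(rng.poisson(rate_per_day)):
            minute = rng.uniform(6 * 60, 22 * 60)
            times.append(day * 1440 + minute)
    return np.sort(np.asarray(times, dtype=float))


def _activity_series(rng: np.random.Generator, config: SimulationConfig,
                     n_minutes: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-minute activity trace and its glucose-lowering effect.

    Exercise bouts arrive about once a day and raise heart rate (or the
    acceleration magnitude) for 30-60 min; the effect channel is the
    normalised excess over rest, which the glucose recursion subtracts.
    """
    excess = np.zeros(n_minutes)
    n_days = max(1, n_minutes // 1440)
    starts = _daytime_event_times(rng, n_days, rate_per_day=1.0)
    for start in starts:
        length = rng.uniform(30, 60)
        s, e = int(start), min(n_minutes, int(start + length))
        if s >= n_minutes:
            continue
        intensity = rng.uniform(0.5, 1.0)
        ramp = np.sin(np.linspace(0, np.pi, e - s)) * intensity
        excess[s:e] = np.maximum(excess[s:e], ramp)
    if config.activity_mode == HEART_RATE:
        trace = 70.0 + 60.0 * excess + rng.normal(0, 2.0, n_minutes)
    else:
        trace = 0.05 + 1.5 * excess + np.abs(rng.normal(0, 0.02, n_minutes))
    return trace, excess


def simulate_patient(config: SimulationConfig,
                     patient_index: int,
                     scripted_meals: list[tuple[float, float]] | None = None
                     ) -> PatientRecord:
    """Generate one complete (gap-free) patient record.

    Deterministic given ``(config.seed, patient_index)``.  Gaps are added
    separately by :func:`inject_gaps` so tests can reason about the clean
    dynamics first.  ``scripted_meals`` — extra ``(minute, grams)`` meals
    injected *without* a covering bolus — exist so single-impulse responses
    of the dynamics can be probed in isolation.
    """
    if patient_index < 0 or patient_index >= config.n_patients:
        raise ConfigurationError(
            f"patient_index {patient_index} outside cohort of "
            f"{config.n_patients}")
    rng = np.random.default_rng(config.seed + patient_index)

    step = config.sample_interval
    n_steps = config.duration_days * 24 * 60 // step
    n_minutes = n_steps * step
    grid = _EPOCH + pd.to_timedelta(np.arange(n_steps) * step, unit="m")

    # meals and the boluses that cover them
    meal_minutes = _daytime_event_times(rng, config.duration_days,
                                        config.meal_rate)
    carb_mean, carb_sd = config.carb_size_distribution
    carbs = np.clip(rng.normal(carb_mean, carb_sd, meal_minutes.size),
                    5.0, None)
    bolus_minutes = meal_minutes + rng.normal(0.0, 7.0, meal_minutes.size)
    bolus_minutes = np.clip(bolus_minutes, 0, n_minutes - 1)
    doses = carbs / config.carb_to_bolus_ratio
    if scripted_meals:
        extra_t = np.asarray([m for m, _ in scripted_meals], dtype=float)
        extra_c = np.asarray([c for _, c in scripted_meals], dtype=float)
        meal_minutes = np.r_[meal_minutes, extra_t]
        carbs = np.r_[carbs, extra_c]

    # drive signals accumulated on the glucose grid
    meal_drive = np.zeros(n_steps)
    k_meal = impulse_kernel(config.meal_absorption_peak, step)
    for t_min, c in zip(meal_minutes, carbs):
        i0 = int(t_min // step) + 1  # effect begins after the meal
        seg = k_meal[: max(0, n_steps - i0)]
        meal_drive[i0:i0 + seg.size] += c * config.carb_gain * seg

    ins_drive = np.zeros(n_steps)
    k_ins = impulse_kernel(config.insulin_action_peak, step)
    for t_min, u in zip(bolus_minutes, doses):
        i0 = int(t_min // step) + 1
        seg = k_ins[: max(0, n_steps - i0)]
        ins_drive[i0:i0 + seg.size] += u * config.insulin_drop * seg

    activity_minute, effect_minute = _activity_series(rng, config, n_minutes)
    effect_grid = effect_minute[::step][:n_steps]

    eps = (rng.normal(0.0, config.noise_sd, n_steps)
           if config.noise_sd > 0 else np.zeros(n_steps))

    glucose = np.empty(n_steps)
    glucose[0] = config.basal_glucose
    k = config.mean_reversion_rate
    for t in range(n_steps - 1):
        nxt = (glucose[t]
               + k * (config.basal_glucose - glucose[t])
               + meal_drive[t + 1]
               - ins_drive[t + 1]
               - config.activity_gain * effect_grid[t]
               + eps[t + 1])
        glucose[t + 1] = min(max(nxt, GLUCOSE_MIN), GLUCOSE_MAX)

    if config.activity_mode == HEART_RATE:
        activity = pd.Series(activity_minute[::step][:n_steps], index=grid,
                             name="activity")
    else:
        minute_grid = _EPOCH + pd.to_timedelta(np.arange(n_minutes),
                                               unit="m")
        activity = pd.Series(activity_minute, index=minute_grid,
                             name="activity")

    carb_df = pd.DataFrame({
        "ts": _EPOCH + pd.to_timedelta(meal_minutes, unit="m"),
        "value": carbs,
    })
    bolus_df = pd.DataFrame({
        "ts": _EPOCH + pd.to_timedelta(bolus_minutes, unit="m"),
        "value": doses,
    })

    split_point = grid[0] + pd.Timedelta(
        days=config.duration_days - config.test_days)
    cohort = "synthetic_hr" if config.activity_mode == HEART_RATE \
        else "synthetic_ma"
    return PatientRecord(
        patient_id=f"sim{patient_index:03d}",
        cohort=cohort,
        glucose=pd.Series(glucose, index=grid, name="glucose"),
        glucose_observed=pd.Series(True, index=grid, name="observed"),
        carb=carb_df,
        bolus=bolus_df,
        activity=activity,
        activity_mode=config.activity_mode,
        split_point=split_point,
        meta={"seed": config.seed, "patient_index": patient_index},
    )


def inject_gaps(record: PatientRecord,
                config: SimulationConfig) -> PatientRecord:
    """Flag randomly placed glucose intervals as missing.

    Gap starts arrive as a Poisson process at ``config.gap_rate`` per day;
    lengths are Gaussian (``gap_length_distribution``, clipped at one
    sample).  Timestamps are never removed — only the observed flag is
    cleared.  Deterministic given ``(seed, patient_index)``.
    """
    if config.gap_rate == 0:
        return record.copy()
    step_min = record.sample_interval.total_seconds() / 60.0
    n = len(record.glucose)
    days = n * step_min / 1440.0
    mean_len, sd_len = config.gap_length_distribution
    expected_missing = config.gap_rate * days * mean_len / (days * 1440.0)
    if expected_missing > 0.5:
        raise ConfigurationError(
            "gap parameters imply more than 50% missing glucose")
    rng = np.random.default_rng(
        int(config.seed) + int(record.meta.get("patient_index", 0)) + 10_000)
    out = record.copy()
    n_gaps = rng.poisson(config.gap_rate * days)
    observed = out.glucose_observed.to_numpy().copy()
    for _ in range(n_gaps):
        start = rng.integers(0, n)
        length_min = max(step_min, rng.normal(mean_len, sd_len))
        span = max(1, int(round(length_min / step_min)))
        observed[start:start + span] = False
    if (~observed).mean() > 0.5:
        raise ConfigurationError("realised missingness exceeds 50%")
    out.glucose_observed = pd.Series(observed, index=out.glucose.index,
                                     name="observed")
    out.meta["n_gap_intervals"] = int(n_gaps)
    return out


def simulate_cohort(config: SimulationConfig,
                    with_gaps: bool = True) -> list[PatientRecord]:
    """Generate the full cohort, optionally with sensor gaps injected."""
    records = [simulate_patient(config, i) for i in range(config.n_patients)]
    if with_gaps:
        records = [inject_gaps(r, config) for r in records]
    return records
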