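"""Ohio-dialect XML serialisation of patient records.

The reader tolerates the attribute spellings used across releases of the
format (``value``/``carbs``/``dose`` for amounts; ``ts``/``ts_begin`` for
timestamps) and logs which elements it matched; unknown elements are
ignored with a log line.  The writer emits a single canonical dialect so a
write-then-read round trip is the identity, letting one reader path serve
both real and synthetic data.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lxml import etree

from .records import ACCEL_MAGNITUDE, HEART_RATE, PatientRecord

__all__ = ["write_ohio_xml", "read_ohio_xml", "write_channels_csv"]

logger = logging.getLogger(__name__)

_TS_FORMAT = "%d-%m-%Y %H:%M:%S"
_ACTIVITY_ELEMENTS = {"basis_heart_rate": HEART_RATE,
                      "acceleration": ACCEL_MAGNITUDE}
_VALUE_ATTRS = ("value", "carbs", "dose")
_TS_ATTRS = ("ts", "ts_begin", "tbegin")


def _fmt(ts: pd.Timestamp) -> str:
    return pd.Timestamp(ts).strftime(_TS_FORMAT)


def write_ohio_xml(record: PatientRecord, path) -> None:
    """Serialise a record to the Ohio-style per-patient XML layout."""
    step_min = int(record.sample_interval.total_seconds() // 60)
    root = etree.Element("patient", id=str(record.patient_id),
                         cohort=str(record.cohort),
                         split_point=_fmt(record.split_point),
                         grid_start=_fmt(record.glucose.index[0]),
                         grid_end=_fmt(record.glucose.index[-1]),
                         grid_step_min=str(step_min))
    glucose = etree.SubElement(root, "glucose_level")
    observed = record.glucose_observed.to_numpy(dtype=bool)
    for (ts, value), obs in zip(record.glucose.items(), observed):
        if obs:
            etree.SubElement(glucose, "event", ts=_fmt(ts),
                             value=f"{value:.10g}")
    meal = etree.SubElement(root, "meal")
    for _, row in record.carb.iterrows():
        etree.SubElement(meal, "event", ts=_fmt(row["ts"]),
                         carbs=f"{row['value']:.10g}")
    bolus = etree.SubElement(root, "bolus")
    for _, row in record.bolus.iterrows():
        etree.SubElement(bolus, "event", ts_begin=_fmt(row["ts"]),
                         dose=f"{row['value']:.10g}")
    act_name = "basis_heart_rate" if record.activity_mode == HEART_RATE \
        else "acceleration"
    act = etree.SubElement(root, act_name)
    for ts, value in record.activity.items():
        etree.SubElement(act, "event", ts=_fmt(ts), value=f"{value:.10g}")
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=True, encoding="utf-8")


def _parse_events(element) -> pd.DataFrame:
    ts_list, values = [], []
    for ev in element.iter("event"):
        ts = next((ev.get(a) for a in _TS_ATTRS if ev.get(a)), None)
        val = next((ev.get(a) for a in _VALUE_ATTRS if ev.get(a)), None)
        if ts is None or val is None:
            logger.warning("skipping event without timestamp/value in <%s>",
                           element.tag)
            continue
        ts_list.append(pd.to_datetime(ts, format=_TS_FORMAT))
        values.append(float(val))
    return pd.DataFrame({"ts": pd.to_datetime(ts_list), "value": values})


def read_ohio_xml(path) -> PatientRecord:
    """Parse an Ohio-dialect XML file into a :class:`PatientRecord`.

    The glucose stream is mandatory; missing grid points between the first
    and last observation are restored as flagged-missing samples.  A file
    without an activity stream yields an empty activity channel and a
    warning.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    known = {"glucose_level", "meal", "bolus", *_ACTIVITY_ELEMENTS}
    for child in root:
        if child.tag not in known:
            logger.info("ignoring unknown element <%s>", child.tag)

    glucose_el = root.find("glucose_level")
    if glucose_el is None or len(glucose_el) == 0:
        raise ValueError(f"{path}: no glucose_level stream")
    gl = _parse_events(glucose_el).sort_values("ts")
    # the canonical dialect records the grid extent so boundary gaps
    # survive a round trip; without it the observed span defines the grid
    if root.get("grid_start"):
        start = pd.to_datetime(root.get("grid_start"), format=_TS_FORMAT)
        end = pd.to_datetime(root.get("grid_end"), format=_TS_FORMAT)
        step = pd.Timedelta(minutes=int(root.get("grid_step_min", 5)))
    else:
        start, end = gl["ts"].iloc[0], gl["ts"].iloc[-1]
        step = gl["ts"].diff().dropna().min()
    grid = pd.date_range(start, end, freq=step)
    series = pd.Series(np.nan, index=grid, name="glucose")
    series.loc[gl["ts"].to_numpy()] = gl["value"].to_numpy()
    observed = series.notna()
    series = series.ffill().bfill()  # placeholders under missing flags

    meal_el = root.find("meal")
    carb = _parse_events(meal_el) if meal_el is not None \
        else pd.DataFrame({"ts": pd.to_datetime([]), "value": []})
    bolus_el = root.find("bolus")
    bolus = _parse_events(bolus_el) if bolus_el is not None \
        else pd.DataFrame({"ts": pd.to_datetime([]), "value": []})

    activity = pd.Series(dtype=float, name="activity")
    activity_mode = HEART_RATE
    for tag, mode in _ACTIVITY_ELEMENTS.items():
        el = root.find(tag)
        if el is not None and len(el):
            ev = _parse_events(el)
            activity = pd.Series(ev["value"].to_numpy(),
                                 index=pd.DatetimeIndex(ev["ts"]),
                                 name="activity")
            activity_mode = mode
            logger.info("matched activity stream <%s>", tag)
            break
    else:
        logger.warning("%s: no activity stream found; channel left empty",
                       path)

    split_attr = root.get("split_point")
    split = pd.to_datetime(split_attr, format=_TS_FORMAT) if split_attr \
        else grid[-1] + (grid[1] - grid[0] if len(grid) > 1
                         else pd.Timedelta(minutes=5))
    return PatientRecord(
        patient_id=root.get("id", "unknown"),
        cohort=root.get("cohort", "unknown"),
        glucose=series,
        glucose_observed=observed.rename("observed"),
        carb=carb,
        bolus=bolus,
        activity=activity,
        activity_mode=activity_mode,
        split_point=split,
    )


def write_channels_csv(record: PatientRecord, path) -> None:
    """Tidy per-channel CSV (timestamp, channel, value, observed) for audit."""
    frames = [
        pd.DataFrame({"timestamp": record.glucose.index,
                      "channel": "glucose",
                      "value": record.glucose.to_numpy(),
                      "observed": record.glucose_observed.to_numpy()}),
        pd.DataFrame({"timestamp": record.carb["ts"], "channel": "carb",
                      "value": record.carb["value"], "observed": True}),
        pd.DataFrame({"timestamp": record.bolus["ts"], "channel": "bolus",
                      "value": record.bolus["value"], "observed": True}),
        pd.DataFrame({"timestamp": record.activity.index,
                      "channel": "activity",
                      "value": record.activity.to_numpy(),
                      "observed": True}),
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
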