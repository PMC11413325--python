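"""End-to-end benchmark orchestration and the printed-table replay path.

``run_benchmark`` drives the full pipeline for a synthetic cohort: for
every (patient x model x input mode x horizon) it preprocesses the record,
fits the forecaster, rolls predictions over the test span and scores them;
the DNN track repeats training over several seeds and records mean +/- sd.
The resulting metric table then feeds the statistical layer.

``replay_printed_tables`` recomputes the statistical layer directly from a
per-patient metric table (such as the transcription of the published
benchmark tables bundled under ``cgmbench/data``) without running any
model — the mechanism for reproducing reference p-values exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import forecast, metrics, nn, preprocess, stats
from .records import PatientRecord, SimulationConfig, split_train_test
from .simulate import simulate_cohort

__all__ = [
    "BenchmarkConfig",
    "load_reported_metrics",
    "run_patient",
    "run_benchmark",
    "replay_printed_tables",
]

logger = logging.getLogger(__name__)

METRIC_DIRECTIONS = {"rmse": "lower", "mae": "lower",
                     "mcc": "higher", "se": "lower"}


@dataclass
class BenchmarkConfig:
    """Configuration of one benchmark run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    models: tuple[str, ...] = ("ctf", "tml", "dnn")
    input_modes: tuple[str, ...] = ("univariate", "multivariate")
    horizons: tuple[int, ...] = (30, 60)
    history_length: int = 12
    alpha: float = 0.05
    hypo_threshold: float = 70.0
    hyper_threshold: float = 180.0
    include_imputed: bool = False
    arima_search_max: int = 2
    ctf_stride: int = 1
    svr_gamma_space: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    svr_C_space: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0)
    svr_epsilon_space: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    dnn_hidden_units: int = 32
    dnn_epochs: int = 30
    dnn_runs: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.models or not self.input_modes or not self.horizons:
            raise ValueError("need at least one model, mode and horizon")
        unknown = set(self.models) - {"ctf", "tml", "dnn"}
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def load_reported_metrics() -> pd.DataFrame:
    """Load the bundled transcription of the published per-patient metrics."""
    with resources.files("cgmbench.data").joinpath(
            "ohio_reported_metrics.csv").open() as fh:
        return pd.read_csv(fh)


def _prepare(record: PatientRecord):
    train, test = split_train_test(
        record, (record.glucose.index[-1] + record.sample_interval
                 - record.split_point) / pd.Timedelta(days=1))
    train_ch, train_imp = preprocess.prepare_channels(train, mode="train")
    test_ch, test_imp = preprocess.prepare_channels(test, mode="test")
    return train_ch, train_imp, test_ch, test_imp


def run_patient(record: PatientRecord, config: BenchmarkConfig,
                seg: metrics.SegGrid) -> tuple[list[metrics.MetricRow],
                                               dict]:
    """Run every configured (model x mode x horizon) cell for one patient."""
    train_ch, _, test_ch, test_imp = _prepare(record)
    rows: list[metrics.MetricRow] = []
    manifest: dict = {"patient": record.patient_id, "cells": []}
    L = config.history_length
    d_verdict = preprocess.determine_d(train_ch["glucose"],
                                       alpha=config.alpha)
    for horizon in config.horizons:
        H = horizon // forecast.STEP_MINUTES
        for mode in config.input_modes:
            frames = {}
            if {"tml", "dnn"} & set(config.models):
                frames["train"] = preprocess.reframe(train_ch, L, H, mode)
                frames["test"] = preprocess.reframe_test(
                    train_ch, test_ch, L, H, mode, test_imputed=test_imp)
            for model in config.models:
                cell = {"model": model, "mode": mode, "horizon": horizon}
                logger.info("patient %s: %s/%s/%d min", record.patient_id,
                            model, mode, horizon)
                if model == "ctf":
                    order = forecast.select_arima_order(
                        train_ch["glucose"].to_numpy(), d=d_verdict.d,
                        search_max=config.arima_search_max)
                    fc = forecast.fit_predict_ctf(
                        train_ch, test_ch, order, horizon, mode,
                        test_imputed=test_imp, stride=config.ctf_stride)
                    cell["order"] = fc.meta["order"]
                    fcs = [fc]
                elif model == "tml":
                    params = forecast.grid_search_svr(
                        frames["train"], config.svr_gamma_space,
                        config.svr_C_space, config.svr_epsilon_space)
                    fcs = [forecast.fit_predict_tml(frames["train"],
                                                    frames["test"], params)]
                    cell["svr_params"] = asdict(params)
                else:  # dnn
                    spec = nn.LstmSpec(
                        history_length=L, horizon_steps=H,
                        hidden_units=config.dnn_hidden_units,
                        epochs=config.dnn_epochs,
                        seed=config.seed * 1000 + hash(record.patient_id)
                        % 997)
                    fcs = nn.dnn_multi_run(frames["train"], frames["test"],
                                           spec, n_runs=config.dnn_runs)
                    cell["lstm_spec"] = {k: v for k, v in
                                         asdict(spec).items()}
                    cell["n_runs"] = config.dnn_runs
                scored = [metrics.score_forecast(
                    fc, seg, record.patient_id,
                    config.hypo_threshold, config.hyper_threshold,
                    config.include_imputed) for fc in fcs]
                mean_row = metrics.MetricRow(
                    patient_id=record.patient_id, model=model,
                    input_mode=mode, horizon=horizon,
                    rmse=float(np.mean([r.rmse for r in scored])),
                    mae=float(np.mean([r.mae for r in scored])),
                    mcc=float(np.mean([r.mcc for r in scored])),
                    se=float(np.mean([r.se for r in scored])),
                    n=scored[0].n,
                )
                rows.append(mean_row)
                if len(scored) > 1:
                    cell["sd"] = {m: float(np.std([getattr(r, m)
                                                   for r in scored]))
                                  for m in METRIC_DIRECTIONS}
                manifest["cells"].append(cell)
    manifest["d"] = d_verdict.d
    return rows, manifest


def metric_table(rows: list[metrics.MetricRow]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in rows])
    return df.rename(columns={"horizon": "horizon_min"})


def run_benchmark(config: BenchmarkConfig,
                  output_dir: str | Path | None = None,
                  records: list[PatientRecord] | None = None
                  ) -> dict:
    """Full pipeline: simulate (unless records given), fit, score, compare.

    Writes the metric CSV, the comparison tables and a run manifest under
    ``output_dir`` when given; always returns them in memory.
    """
    if records is None:
        records = simulate_cohort(config.simulation)
    seg = metrics.synthetic_seg_grid()
    all_rows: list[metrics.MetricRow] = []
    manifests = []
    for record in records:
        rows, manifest = run_patient(record, config, seg)
        all_rows.extend(rows)
        manifests.append(manifest)
    table = metric_table(all_rows)
    reports = replay_printed_tables(table, analysis="friedman",
                                    alpha=config.alpha)
    wilcoxon = replay_printed_tables(table, analysis="wilcoxon",
                                     alpha=config.alpha)
    result = {
        "metrics": table,
        "friedman": reports,
        "wilcoxon": wilcoxon,
        "manifest": {"config": _config_dict(config),
                     "patients": manifests},
    }
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "metrics.csv", index=False)
        reports.to_csv(out / "friedman.csv", index=False)
        wilcoxon.to_csv(out / "wilcoxon.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(result["manifest"], fh, indent=2, default=str)
    return result


def _config_dict(config: BenchmarkConfig) -> dict:
    d = asdict(config)
    d["simulation"] = asdict(config.simulation)
    return d


def _matrix(df: pd.DataFrame, metric: str,
            columns: str) -> stats.BlockedMetricMatrix:
    pivot = df.pivot_table(index="patient_id", columns=columns,
                           values=metric, aggfunc="first")
    if pivot.isna().any().any():
        missing = [(str(i), str(c)) for i, c in
                   zip(*np.where(pivot.isna().to_numpy()))]
        raise ValueError(f"missing cells in {metric} table: {missing}")
    return stats.BlockedMetricMatrix(
        patients=tuple(str(i) for i in pivot.index),
        treatments=tuple(str(c) for c in pivot.columns),
        values=pivot.to_numpy(dtype=float),
        better_direction=METRIC_DIRECTIONS[metric],
    )


def replay_printed_tables(table: pd.DataFrame,
                          analysis: str = "friedman",
                          alpha: float = 0.05,
                          cd_json: str | Path | None = None
                          ) -> pd.DataFrame:
    """Recompute the statistical layer from a per-patient metric table.

    ``analysis="friedman"`` compares models within each (cohort, input
    mode, horizon, metric) cell — Friedman first, Nemenyi + Holm + CD only
    when the omnibus p falls below ``alpha``.  ``analysis="wilcoxon"``
    compares univariate against multivariate input per (cohort, model,
    horizon, metric).  Optionally dumps CD-diagram data as JSON.
    """
    df = table.copy()
    if "cohort" not in df.columns:
        df["cohort"] = "cohort"
    metric_cols = [m for m in METRIC_DIRECTIONS if m in df.columns]
    rows = []
    cd_payload = []
    if analysis == "friedman":
        groups = df.groupby(["cohort", "input_mode", "horizon_min"])
        for (cohort, mode, horizon), sub in groups:
            if sub["model"].nunique() < 2:
                continue
            for metric in metric_cols:
                report = stats.build_model_comparison(
                    _matrix(sub, metric, columns="model"), alpha=alpha)
                rows.append({
                    "cohort": cohort, "input_mode": mode,
                    "horizon_min": horizon, "metric": metric,
                    "friedman_chi2": report.friedman_chi2,
                    "p": report.friedman_p,
                    "significant": report.friedman_p < alpha,
                    "avg_ranks": json.dumps(report.avg_ranks),
                    "cd": report.cd_value,
                    "posthoc": json.dumps([
                        {"pair": list(r["pair"]), "p": r["p"],
                         "significant": r["significant"]}
                        for r in report.pairwise]),
                })
                if report.pairwise:
                    cd_payload.append({
                        "cohort": cohort, "input_mode": mode,
                        "horizon_min": int(horizon), "metric": metric,
                        "treatments": list(report.avg_ranks),
                        "avg_ranks": list(report.avg_ranks.values()),
                        "cd_value": report.cd_value,
                        "cliques": [list(c) for c in stats.rank_cliques(
                            report.avg_ranks, report.cd_value)],
                    })
    elif analysis == "wilcoxon":
        groups = df.groupby(["cohort", "model", "horizon_min"])
        for (cohort, model, horizon), sub in groups:
            modes = set(sub["input_mode"])
            if not {"univariate", "multivariate"} <= modes:
                continue
            uni = sub[sub["input_mode"] == "univariate"] \
                .set_index("patient_id").sort_index()
            multi = sub[sub["input_mode"] == "multivariate"] \
                .set_index("patient_id").sort_index()
            if not uni.index.equals(multi.index):
                raise ValueError(
                    f"unpaired patients for {cohort}/{model}/{horizon}")
            for metric in metric_cols:
                p = stats.wilcoxon_signed_rank(uni[metric].to_numpy(),
                                               multi[metric].to_numpy())
                rows.append({"cohort": cohort, "model": model,
                             "horizon_min": horizon, "metric": metric,
                             "p": p, "significant": p < alpha})
    else:
        raise ValueError(f"unknown analysis {analysis!r}")
    if cd_json is not None:
        with open(cd_json, "w") as fh:
            json.dump(cd_payload, fh, indent=2)
    return pd.DataFrame(rows)
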