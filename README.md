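# cgmbench

A benchmarking pipeline for short-horizon blood-glucose-level (BGL)
forecasting in type 1 diabetes, for researchers comparing forecaster
families on continuous glucose monitoring (CGM) data.

People with type 1 diabetes manage glucose with carbohydrate estimates and
bolus insulin; a model that predicts the CGM reading 30 or 60 minutes
ahead can warn of hypo- and hyperglycaemia early enough to act. Three
data-driven families dominate the literature — classical time-series
forecasting (ARIMA/ARIMAX), traditional machine learning (RBF-kernel
support-vector regression on sliding windows), and deep networks
(sequence-to-sequence LSTM) — and each can be driven by glucose alone
(univariate) or by glucose plus carbohydrate, bolus and physical-activity
channels (multivariate). Because per-patient differences dwarf the
differences between models, comparing cohort averages is not enough:
`cgmbench` pairs every forecast on a common target grid and compares
models with rank-based statistics.

The package provides:

- a **synthetic cohort generator** emulating the structure of the standard
  clinical benchmark records (~8 weeks per patient at 5-minute
  resolution, last days held out for testing, daytime meals each covered
  by a bolus, heart-rate or acceleration activity channels, sensor gaps),
  so the whole pipeline runs without access-restricted data;
- the **preprocessing chain**: causal linear imputation, event
  zero-filling, nearest-point activity alignment, boundary trimming, an
  ADF/KPSS-gated differencing order, and sliding-window reframing;
- the three **forecaster families** behind one fit/predict contract, each
  univariate and multivariate, at 30- and 60-minute horizons, plus a
  persistence baseline;
- **metrics**: RMSE = √(Σᵢ(yᵢ−ŷᵢ)²/N) and MAE = Σᵢ|yᵢ−ŷᵢ|/N (mg/dL), the
  Matthews correlation coefficient of adverse-event detection
  (hypo < 70, hyper > 180 mg/dL), and the surveillance error — the
  bilinearly interpolated mean of a clinical risk surface over
  (reference, predicted) pairs — with colour-coded risk-grid plots;
- the **statistical harness**: Friedman omnibus test on within-patient
  ranks (χ² approximation with tie correction), post-hoc Nemenyi pairwise
  comparisons with Holm step-down correction, the critical difference
  CD = q_α(k)/√2 · √(k(k+1)/6n) for CD diagrams, and the exact two-sided
  Wilcoxon signed-rank test (zeros dropped) for univariate-vs-multivariate
  comparisons;
- an Ohio-style **XML reader/writer**, tidy CSV export, a YAML-configured
  CLI (`cgmbench simulate | run | replay | reference`), and a bundled
  transcription of the published per-patient metric tables so the
  statistical layer can be replayed without restricted data.

See `docs/methods.md` for the models, assumptions and design choices.

## Worked example

Replay the model-comparison layer from the bundled per-patient table —
univariate input, 60-minute horizon, first cohort, RMSE:

```python
from cgmbench import load_reported_metrics, replay_printed_tables

table = load_reported_metrics()
friedman = replay_printed_tables(table, analysis="friedman")
row = friedman.query(
    "cohort == 'Ohio_2018' and input_mode == 'univariate' "
    "and horizon_min == 60 and metric == 'rmse'").iloc[0]
print(f"chi2 = {row['friedman_chi2']:.3f}  p = {row['p']:.4f}")
print("avg ranks:", row["avg_ranks"])
print("cd:", round(row["cd"], 3))
```

prints

```
chi2 = 10.333  p = 0.0057
avg ranks: {"ctf": 3.0, "dnn": 1.8333333333333333, "tml": 1.1666666666666667}
cd: 1.353
```

Reading: across the six patients the support-vector regressor ranks best
(average rank 1.17), the LSTM second (1.83) and ARIMA worst (3.00); the
Friedman test rejects equality of the three families (p ≈ 0.006, printed
as 0.006 in the reference tables), and with a critical difference of 1.35
rank units the 1.83-rank gap between SVR and ARIMA is significant while
the other pairs are not — the post-hoc list in the same row carries the
Nemenyi p-values and Holm decisions.

The same layer runs on tables your own benchmark produces:

```sh
cgmbench run --seed 1 --out results/bench    # synthetic cohort end to end
cgmbench replay results/bench/metrics.csv --analysis wilcoxon
```

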