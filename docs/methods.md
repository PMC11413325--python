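# Methods

`cgmbench` benchmarks data-driven forecasters of blood glucose level (BGL)
in type 1 diabetes. It covers the full experimental loop: generating
patient-like records, the preprocessing chain, three personalised
forecaster families in univariate and multivariate flavours at 30- and
60-minute horizons, regression and clinical scoring, and a rank-based
statistical comparison layer. This note documents the models, the choices
that were genuinely open, and what the synthetic data can and cannot show.

## The synthetic cohort

Real benchmark records of this kind (an ~8-week, 5-minute CGM series per
patient with the last 10 days held out, self-reported carbohydrate and
bolus events, and one wearable activity channel) are distributed only
under a data-use agreement, so the package ships a generator that emulates
their *structure* rather than any patient's physiology.

Glucose follows a discrete-time mean-reverting impulse-response model on
the 5-minute grid:

    G[t+1] = G[t] + k (G_b - G[t])
             + Σ_meals c_m f_meal(t - t_m)
             - Σ_boluses u_b f_ins(t - t_b)
             - a · activity[t] + ε[t],          ε ~ N(0, σ²)

clamped to the sensor range [40, 400] mg/dL. `f_meal` and `f_ins` are
non-negative unimodal gamma-type kernels normalised to unit mass, peaking
at 60 and 75 minutes and truncated at 8 h. Meals arrive as a daytime
(06:00–22:00) Poisson process at 3/day with N(50, 15²) g sizes; each meal
triggers a bolus of carb/ratio units (ratio 10 g/U) with ±7-minute timing
jitter. Exercise bouts (~1/day, 30–60 min) raise the activity channel and
depress glucose. Sensor gaps arrive at `gap_rate`/day with Gaussian
lengths and only clear the observed flag — timestamps are never removed.

Default dynamic parameters were chosen once for realism: basal 120 mg/dL,
per-step noise σ = 5 mg/dL, mean reversion k = 0.035 per 5-minute step
(≈100-minute autocorrelation half-life), +4 mg/dL per gram of
carbohydrate and −32 mg/dL per unit of insulin summed over each kernel.
This yields traces with mean ≈ 135 mg/dL, SD ≈ 28 mg/dL, a few percent of
time above 180 mg/dL and occasional dips below 70 mg/dL, and single-meal
excursions that peak within 3 h and return to basal well before 12 h.

What the generator deliberately reproduces: multichannel structure on the
5-minute grid, genuine cross-channel information (future glucose depends
on recorded carb/bolus/activity, so multivariate forecasters have signal
to find), realistic missingness, and per-patient reproducibility (one
master seed; patient substreams are `seed + patient_index`). What it does
not reproduce: inter-patient physiological heterogeneity beyond the
random streams, circadian basal rhythms, sleep or life events, insulin
stacking, sensor drift/compression artefacts, or the heavy-tailed gap
structure of real devices. Consequently, passing tests demonstrate that
the pipeline is correct and that the models behave as expected on a
well-posed forecasting problem — not that any model achieves a particular
accuracy on real patients.

## Preprocessing

The chain mirrors standard CGM practice: missing glucose/activity values
are interpolated linearly in training spans and *extrapolated* linearly in
test spans (from the last two observations before each gap, so test-time
processing is causal); unreported carb/bolus timestamps mean "no event"
and become zeros on the grid (nearest-point binning, summing collisions so
total grams/units are conserved); a 1-minute acceleration channel is
downsampled by keeping the temporally nearest sample per glucose timestamp
(ties to the earlier sample); channels are trimmed to their common span.

For the classical track, the differencing order d is gated by stationarity
tests at the 5% level: ADF (unit root) and KPSS (level stationarity) are
recorded for the undifferenced series, and d is the smallest order in
{0, 1, 2} whose d-times differenced series passes KPSS. KPSS p-values
outside the tabulated range are clipped to the table bounds.

For the learning tracks the series is reframed as supervised learning:
windows of L past steps (default L = 12, i.e. one hour — the history
length is not pinned by the reference recipe and is a config knob) paired
with the next H glucose values, sliding one step at a time. Test frames
let the earliest windows reach back into the training span so that every
forecaster and the persistence baseline share one target grid per patient
and horizon; metric comparisons are therefore paired by construction.

## Forecaster families

**Classical (CTF)** — ARIMA(p, d, q), or ARIMAX with carb/bolus/activity
as exogenous regressors in multivariate mode. p and q are selected by AIC
minimisation over a grid (full 0–36 supported; scaled-down caps are used
in tests), ties toward smaller p+q then smaller p; d comes from the
stationarity gate. Parameters are estimated by `statsmodels` maximum
likelihood on the training span. Rolling H-step forecasts then use the
ARMA difference-equation recursion: innovations are recovered by the
conditional-sum-of-squares recursion over the full series, future
innovations are zero, forecasts are integrated back through the
differencing and re-centred on the deterministic part. Future exogenous
values over the forecast window use their recorded values — carb and
bolus are known inputs at deployment time. Explosive or non-invertible
fits fall back to (0, d, 0) with a warning.

**Traditional ML (TML)** — a single-output RBF-kernel support-vector
regressor on flattened L×C windows, predicting the glucose value at the
final horizon step (one model per horizon). Inputs and targets are
min-max scaled on the training data and inverse-transformed before
scoring; note the ε-tube therefore lives in scaled target units. The
(γ, C, ε) triple is grid-searched over {0.1, 1, 10, 100} ×
{0.001, 0.01, 0.1, 1} × {0.01, 0.1, 1, 10}, minimising RMSE on the final
20% of the training span (time-ordered, no shuffling); ties prefer
smaller C then smaller γ. The published account of this recipe prints
chosen C values (10, 100) outside its printed C space, suggesting the
space labels are permuted there; the defaults here follow the printed
spaces verbatim and all three are configurable.

**Deep network (DNN)** — a sequence-to-sequence vanilla LSTM implemented
in NumPy (forward pass, backpropagation through time, Adam): one LSTM
layer, one dense ReLU layer, and a linear output emitting all H steps.
He-uniform initialisation, MSE loss, 200 epochs and batch size 32 by
default, initial learning rate 0.01 reduced by ×0.1 after 20 epochs
without validation-loss improvement (final 20% of the training span,
time-ordered). Hidden width is not pinned by the recipe; the package
default is 128 and the test suite uses 32 with reduced epochs to stay
within desk-scale compute. Because initialisation is random, the
benchmark protocol trains over several seeds (default 10) and reports
mean ± sd per metric. Scoring uses the final horizon step.

A persistence baseline (predict the last observation) provides the sanity
yardstick: a forecaster that cannot beat it at 30 minutes has learned
nothing useful.

## Metrics

Per (patient, model, input mode, horizon): RMSE and MAE in mg/dL over the
N scored pairs; the Matthews correlation coefficient of per-timestep
adverse-event detection (adverse = glucose < 70 or > 180 mg/dL, strict
inequalities, thresholds configurable; a zero denominator yields MCC = 0);
and the surveillance error — the mean of a risk surface over (reference,
predicted) pairs, bilinearly interpolated between integer nodes on
[0, 600]² mg/dL. Pairs whose reference value was imputed are excluded by
default (a flag restores them): scoring a model against extrapolated
sensor fills would reward matching the imputation rule, though both modes
are provided because practice varies.

The bundled risk surface is a synthetic stand-in, constructed (not
digitised) because the published consensus surveillance-error-grid lookup
is distributed with its original software and is not redistributable
here. It preserves the structure that matters for every identity the
package relies on — zero diagonal, non-negativity, row-unimodality with
the minimum on the diagonal, 0–4 range, and harsher penalties when the
reference is hypoglycaemic — so SE values are internally consistent and
comparable within this package, but not numerically comparable to scores
computed with the clinical surface.

## Statistical comparison

Model families are compared per cohort, input mode, horizon and metric
with the Friedman test on within-patient ranks (rank 1 = best; lower is
better for RMSE/MAE/SE, higher for MCC). The p-value uses the χ²
approximation with the standard tie correction — the convention that
reproduces this benchmark's reference p-values — with an exact
within-block permutation null available for small instances. Only when
the omnibus p falls below α = 0.05 does the post-hoc layer run: Nemenyi
pairwise p-values from the studentized-range distribution at infinite df
(q = statistic·√2), Holm step-down decisions on the pairwise p-values at
family level α, and the critical difference CD = q_α(k)/√2 · √(k(k+1)/6n)
for CD diagrams. Holm is applied as a step-down on p-values; applying it
to the α ladder instead yields identical decisions.

Univariate-versus-multivariate comparisons use the two-sided Wilcoxon
signed-rank test per model: zero differences are dropped before ranking
(the convention consistent with the reproducible reference values),
absolute differences get average ranks on ties, and the p-value is exact
— computed by a subset-sum convolution equivalent to enumerating all 2ⁿ
sign assignments — for effective n ≤ 25, with the tie-corrected normal
approximation beyond.

The statistical layer runs equally on tables produced by the pipeline and
on any externally supplied per-patient metric CSV (`replay`); the bundled
`data/ohio_reported_metrics.csv` transcribes the published per-patient
values so the reference p-values can be recomputed without restricted
data. Several published Wilcoxon cells (e.g. a printed 0.031 where the
printed-precision differences contain exact zeros) are consistent only
with unrounded internal metric values and cannot be reproduced from the
printed tables; they are documented here and not asserted anywhere.

## Numerical and design choices

- Half-open `[start, end)` intervals everywhere; the train/test boundary
  timestamp belongs to the test side.
- Event binning: nearest grid point, earlier point on exact ties,
  summation on collisions.
- ARIMA: trend `c` when d = 0, none otherwise (glucose has no
  deterministic drift); stability checked via the AR/MA polynomial roots
  with a 10⁻³ margin.
- Grid-search and LSTM validation splits are the final 20% of the
  training span, time-ordered.
- MinMax scaling guards zero-range channels by mapping them to zero.
- Degenerate inputs fail loudly: constant series reject stationarity
  testing, empty scored sets reject metrics, all-tied rank matrices warn
  and return p = 1.
- Scaled-down study sizes in the test suite and acceptance script
  (10–16-day records, 2-day test spans, ARIMA search caps of 1–4, LSTM at
  32 hidden units and 30–60 epochs) are the package's default desk-scale
  conditions; all sizes are configuration, and the full-scale settings
  (56 days, cap 36, 128 units, 200 epochs, 10 runs) remain available.
- The command-line interface exposes `simulate`, `run`, `replay`,
  `reference` and ships YAML config support; the preprocess/train/
  evaluate stages are deliberately not separate subcommands — their
  intermediate artefacts are in-memory library objects, and `run` covers
  the chain end to end.

## Known limitations

- The synthetic cohort's univariate LSTM track is data-starved at
  desk-scale record lengths and does not reliably beat persistence there;
  the multivariate track does. Full-scale records close most of this gap
  but are not run in the default suite.
- The ARIMA recursion conditions on estimated innovations (CSS-style);
  for very short histories its first few forecasts differ slightly from
  full Kalman-filter prediction.
- The surveillance surface is synthetic (above); absolute SE values are
  package-internal.
- Friedman/Nemenyi operate on six-patient blocks as in the reference
  design; with n = 6 and k = 3 only large rank gaps can reach
  significance, which is a property of the design, not of this
  implementation.
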