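# Methods

## Problem and scope

`fedstress` studies binary stress detection from wrist-worn multimodal sensor
data under three learning topologies — individual (one model per user, data
never leaves the device), centralized (raw data pooled on a server, one
model), and federated (FedAvg: only model updates leave the device, one
model) — with logistic regression as the common classifier. Because the
comparison hinges on *who sees whose data*, the package ships a synthetic
cohort generator so that every stage is testable and reproducible without any
external dataset.

## Session model and generator

A session is an ordered sequence of labelled segments. The default protocol
is 2190 s: 1200 s neutral, 600 s stress, 390 s amusement, with per-second
condition labels. Neutral and amusement map to the non-stress class, so the
classification task is binary. `scaled_session_plan(s)` shrinks the protocol
proportionally (integer seconds) for quick experiments.

Channels follow wrist-device export rates: ST and EDA at 4 Hz, the three ACC
axes at 32 Hz, BVP at 64 Hz. These divide the 4/2/1 Hz wavelet targets
evenly, which keeps the multi-rate windowing exact.

The signal model is the simplest one that carries a real, analytically
checkable stress signature:

| channel | model | stress response (scale 1, typical) |
|---|---|---|
| ST | baseline + linear drift (−0.3 °C/session) + noise | −0.4 °C decrement |
| EDA | tonic level + Poisson SCRs (rise τ 0.7 s, decay τ 4 s, ≈0.4 µS) + noise | tonic +1.5 µS; SCR rate 3 → 9 /min |
| BVP | unit sinusoid at instantaneous HR (9 s smoothed) + noise | +18 bpm |
| ACC | gravity offset + noise + movement bursts (2 /min, 2 s, ×20 noise) | none (bursts condition-independent) |

Response magnitudes are plausible wrist-sensor values chosen once; they are
multiplied by a per-participant `stress_effect_scale` and a responder factor
(typical 1, weak 0.5, atypical −1). Atypical responders therefore *reverse*
their EDA/HR response, which is what makes a shared model structurally unable
to fit everyone. At zero noise, every stress-response direction is strictly
testable (tonic EDA mean, SCR rate, mean HR up under stress; reversed for
atypical). Noise defaults: ST 0.05 °C, ACC 0.02 g, EDA 0.03 µS, BVP 0.15 a.u.

Cohorts draw baselines from Gaussian spreads (ST 0.4 °C, EDA 0.8 µS, HR
8 bpm, effect scale 0.35, clamped to physical ranges) and sample responder
type with a configurable atypical fraction (default 0.2). All randomness
flows from a single seed through `numpy.random.default_rng`; identical seeds
give bit-identical cohorts.

What the generator does **not** emulate: realistic PPG pulse morphology, SCR
shape variability and superposition statistics, motion artefacts correlated
with condition, sensor drift/detachment, or the actual distributions of any
real dataset. Passing tests therefore demonstrate correctness of the
pipeline and the *qualitative* topology comparison under controlled non-IID
heterogeneity — not field performance on real recordings.

## Feature pipeline

From each of 7 base streams (ST, ACCx, ACCy, ACCz, ACCnorm = √(x²+y²+z²),
EDA, BVP), 6 variants: original, first and second derivatives, and Haar
discrete-wavelet approximations at 4, 2, 1 Hz — 42 signals (6 ST + 24 ACC +
6 EDA + 6 BVP). A 60 s window slides in 0.25 s steps; each (window, signal)
pair yields 10 statistics — mean, min, max, median, max |x|, variance, SD,
mean absolute deviation, excess kurtosis, skewness — giving 420 features.

Numerical choices, made once and documented rather than inferred:

* **Derivatives** are length-preserving central differences scaled by the
  sampling interval, one-sided at the endpoints (`np.gradient` scheme);
  order 2 applies the operator twice. This keeps all 42 signals aligned to
  the same time axis.
* **"Haar DWT at X Hz"** means the approximation-coefficient cascade
  (a, b) → (a+b)/√2 repeated log2(rate/X) times, so each level halves the
  effective rate; a unit ratio is the identity. Verified against a standard
  wavelet library to 1e-10.
* **Windows** are half-open [start, start+60); a sample at exactly start+60
  belongs to the next window. Because 60 × rate is an integer for every
  effective rate, each window holds exactly 60·r samples. A window is
  stress iff strictly more than half of its covered seconds are stress
  (tie → non-stress, the larger class).
* **Statistics** use population normalization and Fisher excess kurtosis;
  zero-variance windows define skewness = kurtosis = 0 (with a relative
  threshold of 1e-24 · max(|x|,1)² on the second moment, so numerically
  constant windows do not blow up). Each statistic is checked against an
  explicit-loop reference to 1e-12.

Per-window statistics are computed with strided sliding-window views in
chunks (≤ 8M elements), so a full 2190 s participant (8521 × 420) extracts in
roughly 15–20 s and a 6-minute participant in ~2.5 s on one core.

## Classifier

Binary logistic regression on standardized features (per-feature mean/SD
from the training pool; zero-spread features get spread 1 and hence zero
weight contribution). `fit_batch` minimizes the L2-regularized negative
log-likelihood (λ‖w‖²/2, intercept unpenalized, λ = 1 — the common library
default) with L-BFGS on the exact gradient, to a gradient-norm tolerance.
`fit_local_sgd` runs seeded mini-batch gradient descent on the *mean* loss
(λ/n regularization), so its stationary point coincides with the batch
optimum: full-batch descent with a decaying rate converges to the batch fit,
which is tested. The decision threshold is 0.5 with ties going to stress.
Models serialize to JSON losslessly.

## Topologies

All strategies split each participant's windows 80:20 first and evaluate on
identical per-participant test rows. The default split is seeded stratified
random; note that heavily overlapping windows (0.25 s step) make random
splits leak near-duplicates between train and test, which is why
within-participant scores are near-perfect — a `chronological` mode (last
20 % of windows held out) is provided for leak-free evaluation.

* **Individual** — one batch fit per participant on their own training rows.
* **Centralized** — one batch fit on the pooled training rows.
* **Federated** — FedAvg: the server builds the shared standardizer by
  count-weighted pooling of per-client means/variances (no raw rows move),
  initializes a zero model, and for each of 20 rounds (default; 1 local
  epoch, batch 32, learning rate 0.05, all clients participating) collects
  locally updated models and replaces the global weights with the
  sample-count-weighted mean. The server loop is written against an abstract
  client interface exposing only `moments()` and `local_update()`, so the
  privacy contract is structural and testable, not aspirational.

Round/epoch counts are deliberately modest: FedAvg with a simple convex model
and few rounds stays visibly short of the centralized optimum, which is the
regime the comparison probes. All settings are configurable.

## Evaluation

Stress is the positive class. Accuracy, precision, recall and F1 come from
the per-participant confusion matrix; 0/0 denominators yield 0 with a
degeneracy flag so macro averaging stays total. Reports show one row per
participant plus the unweighted (macro) average, rounded half-up to 4
decimals for display while full precision is kept internally. The
class-imbalance pathology is exact and tested: an all-non-stress predictor on
a 90:10 test set scores accuracy 0.9 with F1 = 0.

## Experiment sizes

The seeded comparison experiment defaults to 15 participants, 6-minute
sessions (197/99/64 s), 20 % atypical responders and 5 seeds (~2.5 min on one
core). At that scale the mean-test-F1 ordering individual ≥ centralized ≥
federated holds in 5/5 seeds, with the federated model losing mostly recall —
the same qualitative signature the topology comparison is known for on real
wearable stress data.

## Known limitations

* The generator's simplicity means absolute metric values on synthetic
  cohorts say nothing about real-world accuracy; only orderings and
  structural properties transfer.
* The stratified-random default reproduces the optimistic evaluation common
  in sliding-window pipelines; chronological splitting gives substantially
  harder (more honest) numbers.
* Client sampling (`client_fraction` < 1), secure aggregation, differential
  privacy, client dropout and multiclass labels are out of scope.
* The real-device adapter (`fedstress.wesad`) is an untested experimental
  stub.
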