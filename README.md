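# fedstress

Who should train a stress detector for your smartwatch — you, a central
server, or a federation?

`fedstress` is a reproducible testbed for that question. It implements binary
stress / non-stress detection from multimodal wrist-sensor recordings (skin
temperature, 3-axis accelerometer, electrodermal activity, blood volume
pulse) with logistic regression trained under three topologies:

* **individual** — one model per participant, trained only on their own data;
* **centralized** — one model trained on everyone's pooled data;
* **federated** — a from-scratch FedAvg simulation: each round every client
  updates the global model locally by SGD, and the server replaces the global
  weights with the sample-count-weighted mean
  `w ← Σ_k (n_k / Σ n) · w_k`. Only models and counts cross the client
  boundary, never feature rows — a contract the code enforces structurally.

Because the interesting regime is *non-IID clients* (people respond to
stressors with different intensity, even direction), the package includes a
seeded synthetic cohort generator with per-participant baselines, response
scales, and atypical responders whose electrodermal and heart-rate responses
are sign-flipped. Sessions follow a laboratory stress-induction protocol
(default 2190 s: 20 min neutral, 10 min stress, 6.5 min amusement; neutral
and amusement form the non-stress class).

## Pipeline

1. **Cohort** (`fedstress.cohort`) — multi-rate recordings (ST/EDA 4 Hz,
   ACC 32 Hz, BVP 64 Hz) with per-second condition labels.
2. **Features** (`fedstress.features`) — 42 derived signals (each base
   stream plus ACC magnitude: original, 1st/2nd derivative, Haar wavelet
   approximations at 4/2/1 Hz) × 10 statistics over 60 s windows sliding in
   0.25 s steps = **420 features** per window, with a majority-vote binary
   label.
3. **Models** (`fedstress.logistic`, `fedstress.strategies`) — L2-regularized
   logistic regression on standardized features; batch L-BFGS fits for
   individual/centralized, seeded mini-batch SGD local updates for FedAvg;
   a common per-participant 80:20 split.
4. **Evaluation** (`fedstress.evaluation`) — per-participant confusion
   matrices, Acc = (TP+TN)/N, P = TP/(TP+FP), R = TP/(TP+FN),
   F1 = 2PR/(P+R), and the unweighted macro average across participants.

See `docs/methods.md` for the generator model, all numerical conventions,
and known limitations.

## Worked example

Write a small experiment config:

```yaml
# demo.yaml
seed: 7
output_dir: demo_out
cohort: {n_participants: 4, session_seconds: 360, atypical_fraction: 0.25}
strategies: [individual, centralized, federated]
federated: {rounds: 20}
```

and run the whole pipeline (`simulate`, `extract`, `run`, `report` also work
as separate stages):

```sh
fedstress all -c demo.yaml
```

This simulates four 6-minute participants, extracts 1201 × 420 feature
matrices, trains all three topologies, and writes per-strategy reports. The
comparison table (`demo_out/reports/comparison.csv`) from this exact run:

```
Strategy,Acc,P,R,F1
centralized,0.9979,0.9938,1.0,0.9969
federated,0.9865,0.962,1.0,0.9803
individual,0.999,0.9969,1.0,0.9984
```

and the federated per-participant report (`report_federated.csv`):

```
Participant,Acc,P,R,F1
1,0.9917,0.9753,1.0,0.9875
2,0.9958,0.9875,1.0,0.9937
3,0.9958,0.9875,1.0,0.9937
4,0.9625,0.8977,1.0,0.9461
Average,0.9865,0.962,1.0,0.9803
```

Reading it: individual models fit each participant best, the pooled
centralized model is close behind, and the federated global model trails —
worst on participant 4, this cohort's atypical responder, whose reversed
stress physiology a shared model cannot accommodate. At the full experiment
scale (15 participants, 20 % atypical, 5 seeds,
`fedstress.experiment.comparison_experiment`) the mean-test-F1 ordering
individual ≥ centralized ≥ federated holds in 5 of 5 seeds.

Everything is deterministic under the config seed: rerunning `all` reproduces
every output file byte for byte.

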