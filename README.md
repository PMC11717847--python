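# nanowpt

A digital twin of a wirelessly powered nanowell impedance biosensor, and a
faithful implementation of its readout-analysis pipeline: from coupled-coil
circuit physics, through simulated reagent-addition binding traces, to the
percent-change statistics, feature extraction and SVM classification that
summarize such experiments.

## The system

A nanowell array sensor — micron-scale wells through stacked electrodes,
where protein binding occludes ionic current and changes impedance — sits in
the *secondary* loop of a resonant inductive link (receiver coil, 26 Ω series
resistor).  The *primary* loop (400 mV source, 500 Ω resistor, transmitter
coil, lock-in amplifier) couples to it only magnetically.  Both sides are
tuned to a common resonance near 10.5 MHz via

    L_r = 1 / (ω² C_s)

so that the reflected impedance `Z_refl(ω) = ω² M² / Z_sec(ω)` — the term the
secondary contributes to the equivalent impedance seen from the transmitter —
is maximally sensitive to the sensor.  Reagent additions produce an
instantaneous baseline step of the lock-in output plus a gradual first-order
exponential binding response `a·(1 − e^{−t/τ})` that saturates within
10–15 minutes.  Two relative statistics summarize each step:

* **instantaneous change (%)** = `100·(V(t_after) − V(t_before))/V(t_before)`
* **gradual change (%)** = `100·(V(t₀+400 s) − V(t_add+50 s))/V(t_add+50 s)`,
  with `t₀` the start of the step's recording window and `t_add` the
  addition instant.

Triplicates are summarized by mean ± sample SD and compared with a classical
pooled one-way ANOVA.  For automatic detection, four features — successive
50-s output differences starting 50 s after the step — feed a soft-margin SVM
with a fine-scale Gaussian kernel (`σ = √P/4 = 0.5` on standardized
features).

Because no measured dataset is available, a first-class synthetic-data module
generates every input at the published per-condition statistics (e.g. PBS
fill −54.433 ± 3.37 % step; antibody +2.87 ± 1.19 % and blank-buffer control
−1.2 ± 0.43 % gradual change; 54 experiments, one third protein).

## Worked example

```python
import math
from nanowpt import resonant_inductance, anova_oneway, triplicate_summary
from nanowpt.synthetic import (default_condition_table,
                               simulate_condition_triplicate,
                               analyze_condition_traces,
                               DatasetSpec, generate_dataset)
from nanowpt.classification import split_dataset, train_rbf_svm, evaluate

# 1. resonance design: receiver inductance for the 29.84 fF sensor at 10.5 MHz
l_r = resonant_inductance(29.84e-15, 2 * math.pi * 10.5e6)
print(f"receiver inductance: {l_r * 1e3:.2f} mH")

# 2. simulate an antibody triplicate and summarize the gradual change
table = default_condition_table()
traces = simulate_condition_triplicate(table["antibody"], seeds=[1, 2, 3])
gradual = [s.gradual_change_pct for s in analyze_condition_traces(traces)]
s = triplicate_summary(gradual)
print(f"antibody gradual change: {s.mean:+.2f}% (SD {s.sd:.2f}, n={s.n})")

# 3. compare with a blank-buffer negative-control triplicate
nc = simulate_condition_triplicate(table["nc_blank"], seeds=[4, 5, 6])
nc_gradual = [s.gradual_change_pct for s in analyze_condition_traces(nc)]
f_stat, p = anova_oneway([nc_gradual, gradual])
print(f"one-way ANOVA antibody vs NC: F = {f_stat:.2f}, p = {p:.4f}")

# 4. the 54-experiment dataset and the fine-Gaussian SVM
_, dataset = generate_dataset(DatasetSpec(seed=7))
train, test = split_dataset(dataset, train_fraction=0.7)
report = evaluate(train_rbf_svm(train), test)
print(f"test accuracy: {report.accuracy_pct:.1f}%  AUC: {report.auc:.2f}")
print("confusion matrix (rows=true NC, protein):", report.confusion.tolist())
```

prints

```
receiver inductance: 7.70 mH
antibody gradual change: +2.41% (SD 0.99, n=3)
one-way ANOVA antibody vs NC: F = 32.00, p = 0.0048
test accuracy: 93.8%  AUC: 1.00
confusion matrix (rows=true NC, protein): [[11, 0], [1, 4]]
```

The receiver coil resonating with the 29.84 fF sensor capacitance at
10.5 MHz is 7.7 mH.  The simulated antibody triplicate recovers a gradual
rise near its configured +2.87 % mean, clearly separated from the drifting
negative control (p < 0.01).  On this particular dataset seed one protein
trace drew a weak binding response and was misclassified — per-trace
responses are drawn from the published spreads, which overlap slightly
between classes, so held-out accuracy is 100 % for most seeds but not all
(see `docs/methods.md`).

`FineGaussianSVC` is a scikit-learn estimator, so it composes with sklearn
pipelines, `cross_val_score`, etc.

## Command line

```sh
nanowpt sweep    --out spectrum.csv            # Z_eq(f), 20 Hz - 20 MHz, peak report
nanowpt simulate --seed 3 --out data/          # 54 labelled traces + features
nanowpt analyze  data/traces/trace_000.csv --out stats.json
nanowpt classify --seed 5 --out report.json --roc-out roc.csv
nanowpt run      --seed 7 --out results/       # full pipeline + manifest
```

`run` writes a `manifest.json` recording config and seeds; replaying it
(`nanowpt run --manifest results/manifest.json --out replay/`) reproduces the
report byte-for-byte.

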