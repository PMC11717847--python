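# Methods

This note records the models behind `nanowpt`, the parameters that matter,
and the design choices made where the hardware description leaves the
design genuinely open.

## Circuit model

The wireless link is solved in the phasor domain as two magnetically
coupled meshes.  The primary mesh contains the AC source (0.4 V peak,
10.5 MHz), a 500 Ω resistor, the transmitter coil and the lock-in input;
the secondary contains the receiver coil, a 26 Ω resistor and the nanowell
sensor.  Eliminating the secondary current gives the impedance seen from
the transmitter,

    Z_eq(ω) = R_p + jωL_p + ω²M² / Z_sec(ω),
    Z_sec(ω) = jωL_r + R_sec + Z_sensor(ω),

which a unit test verifies against an independent 2×2 complex mesh solve to
1e-10 relative error over 20 Hz–20 MHz.  `Z_sec = 0` is reported as an
infinite reflected impedance rather than an error.

**Sensor topology.** The nanowell's equivalent circuit is taken as an
access resistance in series with (solution resistance ∥ oxide capacitance)
— the standard reduction for a well whose ionic path is shunted by the
interelectrode dielectric.  A dry sensor is the limit R_sol → ∞.  Defaults:
C_s = 29.84 fF (back-derived from the resonance condition 1/(ω²L) at
10.5 MHz with the 7.7 mH design inductance), R_access = 1 kΩ (a typical
electrode access value; not stated by the hardware description),
R_sol = 10 kΩ for a buffer-filled well.

**Coils and coupling.** Both coils are 35 aligned turns of 0.6 mm wire
with 2 cm² cross-section.  Self-inductance uses the stated design value
7.7 mH rather than a geometric estimate: a filamentary calculation for a
~cm-scale 35-turn air coil gives microhenries, which contradicts the design
value; the printed value is honored as-is and the discrepancy is simply
recorded here.  (With 7.7 mH, ωL_p ≈ 5×10⁵ Ω at 10.5 MHz dominates the
series chain; see the lock-in section.)  Neither the mutual inductance nor
the coil gap is stated, so the coupling coefficient k is a configuration
parameter (default 0.3) and M = k√(L_p L_r); `calibrate_coupling` solves
for the k that makes the simulated loading change of the lock-in output hit
a user-supplied target.

**Magnetics.** Fields and mutual inductances are computed at the
filamentary-loop level: the on-axis field by numeric Biot–Savart
quadrature, the mutual inductance of two coaxial windings by a
Neumann-type double integration (sum over all turn pairs of a numerically
integrated loop-pair kernel; turns stack axially at wire-diameter pitch).
Tests check the loop-pair result against Maxwell's elliptic-integral closed
form to 0.1 %, reciprocity, far-field decay, and the N² scaling of
co-located turns.  The air-gap reluctance is the uniform-flux expression
l_g/(μ A_g).

**Lock-in model.** Readout is quasi-static: at each sample instant
(225 S/s) the circuit is solved at the drive frequency, the loop current is
I = V_src/(Z_eq + R_in), the measured node voltage is I·R_in, and both
demodulated channels pass through a one-pole low-pass at the 2 Hz
bandwidth (time constant 1/(2π·2 Hz) ≈ 0.08 s).  Full time-domain mixer
simulation is out of scope — no mixer details are available.  The input
termination R_in (default 50 Ω) is a model addition: with an ideal series
chain the node voltage would be identically zero.  Note a consequence of
the 7.7 mH inductance: |Z_eq| is dominated by ωL_p off resonance, and
loading the sensor *lowers* |Z_eq| at resonance, which *raises* the node
voltage in this divider.  The recorded hardware shows the output falling on
buffer loading; reproducing that polarity would require unstated parasitics,
so absolute lock-in output levels and signs are explicitly out of the model's
claims.  The qualitative loading fact that *is* asserted (and tested) lives
in the impedance domain: a conductive load lowers the resonance-peak
|Z_eq|.  All readout statistics operate on relative changes of the
simulated output level, which the binding model parameterizes directly.

## Binding-trace model

Each reagent addition contributes an instantaneous fractional step `s` of
the output baseline and a first-order exponential component
`a·(1 − e^{−(t−t_event)/τ})`.  Steps compose multiplicatively (the readout
statistics are ratios); exponentials add:

    V(t) = B · Π(1+s_i) · (1 + Σ a_i(1−e^{−(t−t_i)/τ_i})) · (1 + drift·t) + ε(t)

First-order (Langmuir-like) kinetics are adopted because the observed
responses are exponential with saturation at 10–15 min; τ defaults to
240 s, which puts 95 % of saturation at ≈ 12 min.  Whether the step acts on
the sensor resistance or the output voltage is not distinguishable from the
available description; the model parameterizes the output level, which is
where all statistics are defined.

**Noise.** ε is Gaussian with sd 0.002 of baseline, band-limited by the
instrument's own one-pole 2 Hz filter (the trace *is* the output of a 2 Hz
lock-in sampled at 225 S/s; an unfiltered-iid option exists via
`noise_bandwidth=None`).  The stationary per-sample sd after the band
limit is `NoiseModel.marginal_sd(fs)` ≈ 1.7 × 10⁻⁴ of baseline at the
defaults.  Linear drift is available (`drift_rate`, fraction/s) but
defaults to 0: the synthetic-experiment generator represents *all* drawn
gradual targets — including negative-control drift — through the
exponential term, and a separate default drift would double-count and break
the exact noiseless round trip.  These are calibration knobs emulating
recorded traces, not physics.

## Readout statistics

* instantaneous change % between two instants around the addition; values
  are read as nearest samples (≤ 2.2 ms rounding at 225 S/s, no
  interpolation).  The default "after" instant is the first sample at/after
  the addition, where the step is applied but the exponential is still
  exactly zero, making the noiseless round trip exact.
* gradual change % between the value 400 s after the *window start* and the
  value 50 s after the *addition*; the asymmetry of the two reference
  frames is deliberate and preserved exactly.
* triplicate summaries use the sample SD (n−1).  The pooled (classical)
  one-way ANOVA is used rather than Welch: with exact three-point
  realizations {m−s, m, m+s} of the published group means/SDs it reproduces
  all three published p-values (0.00891, 0.00788, 0.00183) within 5 %,
  which is also the package's check that sample-SD + pooled-ANOVA are the
  conventions those numbers imply.  Implementation is `scipy.stats.f_oneway`;
  tests verify F = t² of an independently coded pooled two-sample t on 100
  random instances.
* event times come from trace annotations; `detect_step` (largest
  single-sample relative jump above 5 %) is a convenience that never
  overrides annotations.

## Synthetic experiments

`default_condition_table()` stores the published per-condition change
statistics, signed: PBS fill −54.433 ± 3.37 % (step); blank-PBS NC
−2.43 ± 1.42 % (step) and −1.2 ± 0.43 % (gradual); antibody +2.87 ± 1.19 %,
purified target +0.96 ± 0.62 %, patient serum +1.61 ± 1.17 %, healthy serum
−3.5 ± 0.28 % (gradual).  Two NC instances were published for the gradual
statistic (−0.87 ± 0.65 and −1.2 ± 0.43); the table stores the protein-step
pair, the one the classification task contrasts.  Conditions whose
instantaneous change was not published carry 0 ± 0 rather than invented
values.  Reagent volumes are protocol metadata and do not enter the model.

Per-trace targets are Normal(mean, SD) draws — the published numbers are
triplicate means/SDs, so normality is an assumption.  The drawn gradual
target g is converted to the exponential asymptote through the closed-form
inverse of the gradual statistic,

    a = g / (E₂ − E₁ − g·E₁),   E₁ = 1−e^{−50/τ},  E₂ = 1−e^{−300/τ},

(addition at 100 s into a 600 s window), so the analysis statistic recovers
g *exactly* in the noiseless limit — the calibration maps asymptote to
statistic through the closed form, not by naive equality.  As τ → 0 both
reference instants sample the saturated level and the mapping diverges;
targets then become unreachable and are reported as errors.

The labelled dataset defaults to 54 single-step experiments, one third
protein (alternating purified-target and patient-serum parameters) and two
thirds negative control (alternating blank-buffer and healthy-serum
parameters); the composition of the real 54-experiment set was not
published beyond the class split, so the alternation is a documented
choice with configurable condition pools.

**What passing tests do and do not show.**  The generator reproduces the
published group statistics and effect sizes, but its traces are cleaner
than reality: no bubbles or fluidic artifacts, Gaussian stationary noise,
perfectly exponential kinetics, and exactly known event times.  Recovery
and classification results on synthetic data therefore bound what the
pipeline can do under the published statistics; they do not certify
performance on raw instrument data.

## Classification

Features are the four successive 50-s raw voltage differences starting
50 s after the instantaneous change (for a pure exponential they form a
geometric sequence with ratio e^{−50/τ}).  The 70/30 split of 54 is
non-integer; the train side is the nearest integer (38/16), stratified by
class (13/25 + 5/11) — stratification is a documented choice for balance
at this size.  The "fine Gaussian" kernel scale is √P/4 = 0.5 on
standardized features, box constraint C = 1, both configurable;
standardization is on by default.  ROC treats protein as positive.

**Accuracy under the published spreads.**  Drawing per-trace gradual
targets from the published Normal spreads makes the class populations
overlap: patient serum (+1.61 ± 1.17 %) crosses zero at 1.4 SD, so ≈ 8 % of
patient-serum draws present a negative-control-like response, and the
purified-target/blank-NC pair contributes a few percent more.  The Bayes
error per test sample is therefore ~2 %, and with 16 held-out samples the
probability that a run scores exactly 100 % is ≈ 0.6–0.7 — measured: 63 of
100 seeds (watch `tests/test_acceptance.py`).  A claim of 100 % accuracy in
≥ 95 % of replicates is not attainable under these spreads; the
corresponding check is left failing rather than weakened, since softening
it would misrepresent what the published statistics imply.  Permuting
labels collapses accuracy to the 66.7 % majority rate, confirming the
signal is real.

## Numerical choices

* Loop-pair Neumann integrals: adaptive quadrature (`scipy.integrate.quad`,
  rel. tol 1e-11); accurate for separations at or above the wire diameter,
  warned below it.
* Frequency sweeps use log-spaced grids; the peak is the maximum of |Z_eq|
  with ties broken toward the lowest frequency.
* Strict SI internally; configuration accepts engineering suffixes
  (fF, mH, MHz, cm²) parsed at the boundary, with area prefixes squared.
* All randomness flows through `numpy.random.SeedSequence` spawning: one
  root seed determines protocol draws, noise streams and the train/test
  split; reports are byte-identical across replays (manifests carry
  timestamps, reports do not).
* Degenerate inputs raise typed errors (invalid geometry/parameter,
  insufficient data, undefined ratio, out-of-range instant) rather than
  propagating NaNs.

## Known limitations

* No mass-transport or dose–response modelling: amplitudes come from the
  published per-condition statistics, not from concentrations.
* The circuit stage does not reproduce absolute impedance-spectrum values
  or the output-drop polarity of the recorded hardware (unstated
  parasitics); it provides the qualitative resonance and loading behavior
  plus exact internal consistency.
* Coil misalignment/tilt, temperature effects and instrument drivers are
  out of scope.
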