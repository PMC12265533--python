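# Methods

This note documents the models, the synthetic-data generators, the
numerical choices, and their rationale. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Dual-process signal-detection (DPSD) model

Recognition confidence responses (six ordinal bins, 1 = surely-new …
6 = surely-old) are modeled as a mixture of two processes. With
probability `R` an old probe is *recollected* and produces the
highest-confidence old response (bin 6) — the classic all-or-none
identification; otherwise its memory strength is drawn from `N(F, 1)`
and compared to five ordered criteria `c1 < … < c5`. New probes draw
from `N(0, 1)`; recollection never occurs for new probes (the
false-recollection parameter is fixed at 0). The cumulative operating
points are

```
HR(c)  = R + (1 − R)·Φ(F − c)
FAR(c) = 1 − Φ(c)
```

and bin probabilities are successive differences of these cumulative
functions; per class they sum to 1 to machine precision for every valid
parameter set (property-tested). The likelihood of a participant ×
condition cell is the product of two multinomials (old and new probes).
Degenerate parameter values that put zero mass on an observed bin yield
`−inf` log-likelihood (signaled, not raised), which random-walk
Metropolis simply rejects.

## Hierarchical structure and priors

Participant-level parameters live on transformed scales so that every
draw respects the constraints:

* recollection: probit (`rho = Φ⁻¹(R)`),
* familiarity: identity,
* criteria: first criterion + log-increments (guaranteeing order).

Each transformed parameter is `Normal(population mean, random-effect
SD)`; the linear predictor is the sum of the fixed (condition) and
random (participant) effects, and the variability term is the
participant-by-condition interaction SD (one SD for recollection, one
for familiarity, one per criterion coordinate). Criteria are
participant-level with population means and are **shared across
conditions within a participant**: the experiment is blocked on the same
response dial, so the response scale is a property of the participant,
not the condition. This choice is switchable in principle (the model
consumes a counts tensor; a per-condition-criteria variant would enlarge
`gamma`), but it is the default and the tested configuration.

Priors are weakly informative: `Normal(0, 1.5)` on population means
(transformed scales) and `HalfNormal(1)` on random-effect SDs, both
overridable via `DPSDPriors`. At the data sizes of interest (≥ 100
trials per cell, ≥ 8 participants) the posterior is dominated by the
likelihood.

## Sampler

No general-purpose NUTS implementation is available in the target
environment, and the posterior is ~350-dimensional with a hierarchical
funnel, which rules out ensemble samplers. The package therefore ships
an adaptive **Metropolis-within-Gibbs** sampler written for exactly this
model:

* scalar random-walk Metropolis on every participant-level coordinate,
  vectorized across participants and conditions; proposal scales adapt
  toward 44% acceptance during warmup (Robbins–Monro on the log scale);
* repeated sweeps (default 3 per iteration) of the recollection /
  familiarity cells plus a **joint anti-correlated (ρ, f) proposal**
  along the likelihood ridge (R trades off against F within a cell);
* conjugate Gibbs draws of the population means;
* random-walk Metropolis on the log random-effect SDs, plus a
  **parameter-expansion rescale move** that jointly scales a set of
  random effects and their SD (log-ratio = Δloglik + ε − Δ half-normal
  prior), which crosses the funnel that otherwise stalls the SD chains.

Presets: `full` = 4 chains × 12,000 warmup / 12,000 draws (high-fidelity
budget), `acceptance` = 4 × 5,000/5,000 (the reduced preset used by the
recovery protocols; ~50 s for 31 × 3 × 120 trials on one CPU), `test` =
4 × 1,000/1,000 (seconds; used throughout the test suite). Every fit
takes an explicit seed; chains receive independent spawned streams and
jittered data-driven starting values, so runs are exactly reproducible
and chains are genuinely overdispersed for the R̂ diagnostic.

Convergence is summarized by the split-chain Gelman–Rubin statistic and
(arviz) bulk effective sample size; any population-level R̂ above 1.1
flags the results object as non-converged (a warning, not an error —
results are still returned for inspection).

Population summaries default to the fixed-effect chain (`R = Φ(μ_ρ)`);
averaging participant-level draws per sample is exposed as an
alternative (`population="participant_mean"`). The two agree closely on
all tested data.

## Behavioral statistics

Hit/false-alarm rates use exact rational arithmetic on counts before
conversion to float, so Cowan's `K = N·(H − FA)` is exact; below-chance
`K` is retained (no truncation). An "old" response is any bin ≥ 4 (the
OLD half of the dial). The dial-to-bin mapping divides each 90° response
arc into three 30° bins, rejects the two 90° gap regions, and assigns
boundary angles to the lower-numbered bin (deterministic tie-break on a
measure-zero event).

Repeated-measures ANOVAs (one- and two-way, uncorrected p with integer
degrees of freedom, partial eta squared) are computed through pingouin;
the test suite checks them against an independent brute-force
sums-of-squares decomposition to 1e-10 relative error. A fully
degenerate effect (zero effect and zero error SS) is reported as F = 0,
p = 1. Paired comparisons use Bonferroni correction (p × number of
pairs, capped at 1) and Cohen's d = mean difference / SD of differences
(equivalently t/√n). A zero-variance difference with nonzero mean raises
a degenerate-test error; with zero mean it returns t = 0, p = 1, d = 0.

## CDA pipeline

Epochs (−200…2000 ms at 500 Hz by default) are baseline-corrected to the
−200…0 ms mean per channel per epoch — standard ERP practice; disabling
the correction is a keyword away. The CDA is the contralateral-minus-
ipsilateral mean over the pairs P3/P4, P7/P8, PO3/PO4, PO7/PO8, averaged
over window samples with a half-open `[start, end)` sample convention,
so the combined 400–2000 ms value is exactly the time-weighted sample
mean. Windows: encoding 400–1000 ms, delay 1400–2000 ms, combined
400–2000 ms.

Artifact detectors and thresholds: EOG |V| > 50 µV; EOG step > 30 µV
(100-ms windows, 10-ms steps); gaze step > 0.5° (100/10 ms; skipped with
a notice when gaze channels are absent — EOG is the fallback); drift =
fitted line with |total fitted change| > 75 µV **and** R² ≥ 0.3;
peak-to-peak > 75 µV (200/100 ms); |V| > 100 µV; EEG step > 60 µV
(150/10 ms); flatline = zero variance over the epoch (span
configurable — the criterion's exact duration is a free choice here).
Step detectors use the half-window mean-difference form (mean of the
second half-window minus mean of the first); windows advance on sample
indices and partial trailing windows are skipped. Every detector is
tested for exact agreement with a brute-force per-window loop. A trial
is rejected when any detector fires; participants with **strictly more
than 30%** of trials rejected are excluded. Rejection masks are kept
separate from behavioral data (artifact rejection never removes
behavioral trials).

The additivity test runs the stimulus-type × set-size repeated-measures
ANOVA on participant cell means of one window and renders a verdict at a
configurable α = .05: *interactive* if the interaction is significant,
else *additive* if the stimulus-type main effect is significant, else
*indeterminate*.

## Synthetic-data generators

**Recognition** (`DPSDPopulationSpec`): population recollection 0.35 in
every condition and familiarity 0.93 / 0.91 / 1.10 (repeated colors /
repeated objects / trial-unique objects); 31 participants × 120 trials
per condition, probes old/new with equal probability — the desk-scale
recovery conditions. Between-participant SDs (0.08 on each transformed
scale) are fixture choices: no empirical variance estimates exist to
copy, and "small" spread keeps the population means interpretable.
Criteria means (−1.2, −0.2, 0.85, 1.8, 2.9) span the whole rating scale
with a conservative top criterion (< 1% surely-old false alarms), as in
typical confidence-rating ROC data; at the old/new midpoint they
reproduce hit ≈ 0.74 and false-alarm ≈ 0.20. The conservative top
criterion matters: it is what lets bin-6 counts pin recollection
sharply, and with it the simulate-and-refit protocol recovers population
means within ±0.10 and separates the trial-unique familiarity interval
from the repeated-condition intervals. A single 120-trial-per-cell
dataset still carries ~0.05 SD of trial-sampling noise on each
familiarity estimate (the R–F likelihood ridge), so the acceptance
script averages three replicate datasets, and the interval-separation
event — though it holds at the suite's fixed seed — is not guaranteed on
every seed.

**Change detection** (`CapacityObserverSpec`): fixed-capacity observer —
the probed item is in memory with probability `min(K/N, 1)`; in-memory
probes are answered correctly, otherwise the observer guesses "change"
with the guess rate (0.5), with an optional lapse rate. `K = N·(H − FA)`
recovers `min(K, N)` in expectation (tested to 0.05 at 10⁵ trials).
Capacity may vary per stimulus type and per participant (truncated
normal at 0).

**Lateralized ERP** (`ERPSimSpec`): 500 Hz, −200…2000 ms, set sizes
1/3/5 × {repeated colors, trial-unique objects}, 18 participants × 200
trials per cell by default (the recording-scale design; tests and the
calibration protocols pass smaller sizes explicitly; data are float32).
The CDA waveform ramps from 200 to 400 ms and holds through 2000 ms, so
its window means equal the programmed amplitude exactly;
contralateral amplitude is `a·min(N, K_plateau) + δ(type)` with
a = −0.8 µV/item, K_plateau = 3 items and δ = −0.5 µV for objects
(additive regime). Distinct per-type plateaus produce the
capacity-expansion (interactive) regime. A common bilateral evoked
response (−1 µV) underlies both hemispheres and cancels exactly in the
contra−ipsi difference. Noise is Gaussian at 10 µV RMS with **1/f
(pink) spectral shaping by default**: EEG background power is
low-frequency dominated, and spectrally flat noise of equal RMS is
unrealistically spiky — at 10 µV RMS it trips the 75 µV peak-to-peak
detector on ~7% of artifact-free trials, whereas pink noise yields the
realistic ~0.5% false-positive floor. White noise remains available
(`noise_exponent=0`).

Artifacts are injected per class at configurable rates with ground-truth
labels: blink = 400-ms biphasic VEOG deflection, saccade = HEOG step
(plus a 1° gaze step when gaze channels are simulated), drift = linear
ramp, muscle = 300-ms band-limited 40–70 Hz burst, step = DC shift,
flatline = zeroed channel. Default amplitudes are 1.5× the corresponding
detection threshold, so injected artifacts are detectable by
construction and labeled data support sensitivity / false-positive
measurement.

### What the generators do and do not emulate

They reproduce the statistical structure the analyses assume: ordinal
confidence data from the DPSD mixture with participant heterogeneity, a
saturating lateralized amplitude function with additive or interactive
type effects, spectrally realistic stationary noise, and
threshold-exceeding artifact morphologies. They do **not** emulate real
EEG topography or volume conduction, non-stationary or correlated-
across-channel noise, overlapping ERP components, eye-movement artifacts
time-locked to task events, serial dependencies or learning across
trials, or proactive-interference dynamics as a process (condition
differences are injected directly as parameter differences). Passing
tests therefore demonstrate correctness of the estimators and detectors
under the stated models, not robustness to every property of recorded
data.

## Calibration protocols and problem sizes

The additivity test's type-I error is measured on 500 simulated null
experiments (additive generator, 8 participants × 8 trials per cell —
the F-test's size does not depend on the design size, so the null
calibration uses a small, fast design) and its power on 50 experiments
from the capacity-expansion generator at 16 participants × 30 trials per
cell with matched noise. Detector/oracle agreement uses 100 random
heavy-tailed epochs; closed-form vs Monte-Carlo ROC agreement uses 20
random parameter sets × 10⁶ trials. These sizes keep the full suite and
the acceptance script to a few minutes each on a single CPU.

## Known limitations

* The sampler is specialized to this model family; it is not a
  general-purpose MCMC engine, and its mixing relies on the ridge and
  funnel moves described above.
* Unequal-variance signal detection, model comparison (WAIC/LOO), and
  mixture models of continuous-report error are out of scope.
* The EDF reader is a thin epoching helper (requires mne and explicit
  event times); online referencing, filtering and ICA are treated as
  properties of the input recording, not re-implemented.
* With ~120 trials per cell, recollection and familiarity are partially
  confounded per participant; population inference is correspondingly
  noisier than the per-parameter HDIs alone suggest (see the replicate
  averaging above).
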