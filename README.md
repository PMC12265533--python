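# wmcda

Analysis toolkit for visual working-memory experiments that combine
confidence-rating recognition with lateralized EEG: a hierarchical
Bayesian **dual-process signal-detection (DPSD)** model of recognition
ROCs, and a **contralateral delay activity (CDA)** pipeline with
rule-based artifact rejection and a set-size × stimulus-type additivity
test. Synthetic-data generators reproduce the statistical structure both
analyses assume, so the entire pipeline runs and is tested without any
recorded data.

## Who this is for

Researchers studying visual working-memory capacity who want to separate
*how many items are actively stored* from *how much long-term-memory
familiarity contributes to recognition*. The two engines address the two
halves of that question:

1. **Behavior / DPSD** — confidence-rating recognition data are binned
   into six ordinal levels and modeled as a mixture of all-or-none
   recollection and continuous familiarity:

   `HR(c) = R + (1 − R)·Φ(F − c)`, `FAR(c) = 1 − Φ(c)`

   where `R` is the recollection probability, `F` the familiarity
   strength (d′-like), and `c1 < … < c5` the ordered response criteria.
   Parameters are estimated hierarchically (population means + per-
   participant random effects on probit / identity / log-increment
   scales) by MCMC, with split-chain Gelman–Rubin R̂, effective sample
   size, and shortest 95% highest-density intervals.

2. **EEG / CDA** — epoched lateralized EEG is screened by a suite of
   sliding-window artifact detectors (EOG absolute/step, gaze step,
   linear drift, peak-to-peak, absolute voltage, EEG step, flatline),
   participants with > 30% rejected trials are excluded, and the CDA is
   the contra-minus-ipsilateral mean over P3/P4, P7/P8, PO3/PO4, PO7/PO8
   in the encoding (400–1000 ms), delay (1400–2000 ms) and combined
   (400–2000 ms) windows. A two-way repeated-measures ANOVA on
   stimulus-type × set-size cell means renders an *additive* /
   *interactive* / *indeterminate* verdict — additive offsets indicate a
   stimulus-driven effect, an interaction indicates a change in the
   number of stored items.

Capacity is summarized throughout with Cowan's K = N·(hit − false-alarm).

## Worked example

```python
from wmcda.synth import DPSDPopulationSpec, gen_recognition_trials
from wmcda.dpsd import HierarchicalDPSD

trials = gen_recognition_trials(DPSDPopulationSpec(seed=1))
model = HierarchicalDPSD.from_dataframe(trials)
results = model.fit(preset="test", seed=1)
print(results.summary().round(3).iloc[:6])
```

```
             mean  hdi_2.5%  hdi_97.5%   rhat      ess
parameter
R[CLR_REP]  0.334     0.305      0.365  1.016  627.442
R[OBJ_REP]  0.325     0.295      0.355  1.003  632.518
R[OBJ_UNI]  0.353     0.322      0.385  1.016  317.326
F[CLR_REP]  0.916     0.838      0.984  1.089   44.345
F[OBJ_REP]  0.839     0.768      0.907  1.090   39.641
F[OBJ_UNI]  1.136     1.065      1.218  1.052   75.705
```

The generating population values were R = 0.35 in every condition and
familiarity 0.93 / 0.91 / 1.10 for repeated colors, repeated objects and
trial-unique objects: the quick `test` preset already recovers
recollection within ±0.03 and familiarity within ±0.09, and the
trial-unique familiarity interval sits above both repeated-condition
intervals — the dissociation pattern (stable recollection, selectively
elevated familiarity) the model is designed to detect. The longer
`acceptance`/`full` presets push all R̂ below 1.05.

For the EEG side:

```python
from wmcda.synth import ERPSimSpec, gen_erp_epochs
from wmcda.cda import reject_and_exclude, compute_cda, test_additivity

spec = ERPSimSpec(n_participants=12, n_trials_per_cell=16, noise_rms=4.0,
                  type_offset={"CLR_REP": 0.0, "OBJ_UNI": -1.0}, seed=1)
report, kept, _ = reject_and_exclude(gen_erp_epochs(spec))
verdict = test_additivity(compute_cda(kept))
print(verdict.anova.round(3)); print(verdict.verdict)
```

```
                 effect       F  df1  df2      p    np2
0             stim_type  61.749    1   11  0.000  0.849
1              set_size  78.542    2   22  0.000  0.877
2  stim_type * set_size   0.519    2   22  0.602  0.045
additive
```

A constant −1 µV stimulus-type offset with a common capacity plateau
produces a significant type main effect, a significant set-size effect,
and no interaction: the additive signature.

A `wmcda` command-line interface wraps the generators and analyses
(`wmcda synth … | behavior … | dpsd fit | cda … | run exp1|exp2`).

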