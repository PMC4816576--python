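# Methods

This note documents the models, calibrations and numerical choices behind
`erpdecode`: what the simulator generates and why, how every analysis stage
is defined, and what the shipped defaults do and do not demonstrate.

## The generative model

Each simulated trial is a response-locked epoch
(default −200 … +798 ms at 500 Hz, i.e. 500 samples — a 1 s epoch with the
response at time 0; no baseline correction is applied anywhere in the
pipeline):

```
x(trial, ch, t) = Σ_components  s_comp(subject) · A_comp(response)
                  · exp(−(t − t_peak)² / 2w²)        (temporal bump)
                  · exp(−d(ch, peak_ch)² / 2σ_s²)    (spatial falloff)
                  + noise(trial, ch, t)
```

- **Components.** Ne/ERN: Gaussian bump peaking 70 ms post-response
  (temporal SD 25 ms) at FCz; Pe: 220 ms (SD 35 ms) at Cz. The real
  components are asymmetric deflections; a Gaussian is the simplest
  unimodal shape with a closed-form window mean, which makes every
  downstream quantification analytically checkable. Amplitudes differ by
  response (error ≫ correct for both components; the small correct-trial
  Ne is the CRN analog, amplitude −2 μV against the error amplitude
  calibrated below).
- **Topography.** Isotropic Gaussian falloff over Euclidean distance on a
  schematic 2-D montage (59 labelled 10-10 positions with mastoids;
  σ_s = 0.40 for Ne, 0.45 for Pe, head radius 1). Real topographies arise
  from volume conduction of dipolar sources and are not radially
  symmetric; the falloff only needs to make neighbouring feature
  electrodes carry correlated, attenuated copies of the component, which
  it does.
- **Between-subject variability.** One lognormal amplitude scale per
  component per subject (σ = 0.35, mean fixed to 1 so population-level
  expectations stay calibrated), shared across the two tasks. This makes
  some subjects Ne-driven and others Pe-driven, and gives the per-subject
  spread of decoding accuracies seen in the report tables.
- **Noise.** Channel-independent white noise (SD 7 μV/sample) + 1/f
  ("pink") noise (SD 16 μV/sample) + a 10 Hz rhythm with random phase
  (SD 3 μV). Real EEG background is spatially correlated and
  non-stationary; channel-independence makes multi-electrode features
  slightly more informative than they would be in recorded data, which is
  one reason the simulator's accuracy level is a calibration, not a
  prediction.
- **Behaviour.** Trial count per subject/task uniform in 480–640 (seven
  80-trial blocks ± variation); error trials i.i.d. Bernoulli (rates
  below); RTs Gaussian, truncated to (100, 1000) ms by resampling.

### Calibration of the defaults

Expected windowed-mean differences have the closed form
`(A_error − A_correct) · ḡ`, where `ḡ` is the mean of the unit bump over
the discrete measurement window. `make_default_config` inverts this to set
amplitudes so that the *flanker-task* expected error−correct differences
are exactly **10.15 μV** in the Ne window (20–100 ms at FCz) and
**3.97 μV** in the Pe window (180–250 ms at Cz). Rotation-task separations
are attenuated to 60 % of the flanker values — the attenuation factor is a
free choice fixing only the direction of the task × accuracy interaction,
since only that direction (flanker > rotation) is constrained. Error
rates are 13.87 % / 17.67 % and RT means 242/311 ms (flanker
error/correct) and 436/446 ms (rotation), with RT SDs of 60/90 ms (means
are constrained; SDs are chosen as plausible speeded-task spreads).

The noise SDs were calibrated once so that single-subject combined-feature
10-fold CV decoding lands in the mid-80s % within the flanker task and the
mid-70s % within the rotation task, with across-task transfer around
70 %. The single-trial signal-to-noise ratio of real Ne/Pe data is not
identifiable from condition means, so this calibration is a documented
property of the configuration — passing accuracy-band tests shows the
pipeline and calibrated simulator are jointly consistent, not that real
recordings would yield these numbers.

## Preprocessing

- **Filter.** Linear-phase FIR band-pass 0.5–25 Hz (Hamming-window design,
  ~0.8 s of taps by default), applied centred with reflection padding so
  the group delay is compensated exactly (zero-phase output). On 1 s
  epochs the 0.5 Hz edge necessarily has a wide transition band; the
  pipeline therefore does not filter simulator output by default (it is
  already band-limited, and the high-pass edge would bias the calibrated
  window means); the stage exists for recorded/continuous data.
- **Re-referencing.** Mean of M1/M2 subtracted from every channel.
- **Artifact rejection.** Mean and SD pooled over all data points of all
  scalp channels (mastoids excluded); a trial is flagged if any point
  exceeds ±3 SD; at most ⌊5 % · n⌋ trials are removed, ranked by each
  trial's maximum |z| with ties broken towards the earlier index. A zero
  pooled SD (constant data) rejects nothing.
- **RT exclusion.** Strict: only trials with 100 < RT < 1000 ms survive.
- **Ocular artifacts.** Not simulated and not removed; `ica_hook` is the
  seam where an external cleaner (e.g. an ICA-based tool) can be plugged
  into the stage sequence.

## ERP quantification and statistics

Windows are endpoint-inclusive on the discrete grid. The 2×2
repeated-measures ANOVA is computed through orthogonal paired contrasts —
in a fully-within 2×2 design each effect's F is exactly the squared paired
t on its contrast, with df (1, n−1) and η_p² = F/(F + n − 1); the test
suite cross-checks against an independent general implementation
(pingouin). Bootstrap paired t-tests resample the mean-centred paired
differences (add-one p estimator); Cohen's d for repeated measures is
mean(diff)/SD(diff) — one of several variants in use, chosen for its
direct correspondence to the paired t. Benjamini–Yekutieli adjustment is
delegated to statsmodels (hand-computed oracle values in the tests). ERP
images scale each subject's single trials to [−1, 1] by the subject's
maximum absolute value, sort by RT, and smooth down the trial axis with a
40-trial boxcar.

## Classification scheme

Features are per-trial windowed mean voltages (Ne electrodes × Ne window,
Pe electrodes × Pe window, or both concatenated → 5/5/10 features). For
every analysis: all error trials are kept and an equal-sized random sample
of correct trials is drawn (without replacement), so chance is 50 % and
accuracy = 100·(correct classifications)/(balanced set size).

- **Scaling.** Min–max to [0, 1], fit on the training partition only and
  applied with clipping to held-out/transfer data. Fitting on the whole
  set before CV would leak; train-only fitting is a deliberate
  strengthening of the usual "scale to [0, 1]" recipe (constant features
  map to 0.5). A `scale_jointly` switch (``--scale-jointly`` on the CLI)
  reproduces whole-set scaling for comparison.
- **Hyperparameters.** Nested grid search: coarse C ∈ 2^(−5…15),
  γ ∈ 2^(−15…3) in steps of 2²; then a 9×9 fine grid ±2 powers of two
  around the coarse optimum in steps of 2^0.5. Folds are identical across
  grid points; exact accuracy ties go to the smallest C, then smallest γ.
- **Within-task.** Stratified 10-fold CV, pooled accuracy over all
  held-out trials (so reported accuracy is exactly 100·n_correct/n_total).
- **Across-task.** Hyperparameters and scaler from the (balanced)
  training task; final SVM fit on the full balanced training set; tested
  on the balanced trials of the other task.
- **Significance.** Label-randomisation test, default 1000 permutations,
  p = #{permuted ≥ observed}/n_perm (plain proportion, so p = 0 is
  attainable; an add-one estimator is available). Within-task permutations
  re-run the 10-fold CV with hyperparameters fixed at the observed
  selection (re-searching per permutation is available behind
  `full_refit=True` but is ~190× slower and changes little: fixing the
  hyperparameters is itself permutation-invariant conditional on the
  observed data). Transfer permutations permute the test-set labels of
  the fixed trained model.
- **Repeats.** The scheme is repeated 10 times (default) with freshly
  drawn correct-trial samples; tables report mean/min/max of accuracy and
  p (plus correctly-classified trial counts and the balanced total for
  transfer modes). The "p (mean)" aggregate is the arithmetic mean of the
  10 p-values.

Error is the positive class throughout. All fold assignment, balancing,
and permutation draws are seeded; a repeat's seed derives from the master
seed via `numpy.random.SeedSequence`, so every report is bit-reproducible
from its manifest.

## Evaluation runs and problem sizes

`erpdecode.evaluation` measures the package's headline quantities on
freshly simulated cohorts; `scripts/acceptance.py` and the acceptance
tests call these routines. Problem sizes are chosen as the smallest that
estimate each quantity with useful precision:

- behavioural summary: 50 subjects × 2 tasks (metadata only, noise off);
- ERP effect recovery: 200 flanker subjects, full default trial counts
  (Monte-Carlo SE of the grand-average Ne difference ≈ 0.26 μV);
- decoding bands: 10 subjects, 1 repeat per mode, 200 transfer
  permutations;
- null calibration: 200 independent subject-runs of the label-null
  configuration (amplitude_error = amplitude_correct), 200 permutations
  each, at a reduced 160–200 trials/subject, with fixed default
  hyperparameters (C = 1, γ = 0.1) — a grid search per permutation adds
  nothing to a type-I-error estimate.

These evaluation runs (and the heavier tests) use a reduced montage
holding the eight Ne/Pe feature electrodes plus the mastoids: with
channel-independent noise, channels outside the feature set influence
nothing downstream except artifact-rejection pooling.

The null-calibration CV additionally trims each class to a multiple of the
fold count before splitting, making every fold exactly class-balanced.
Without this, k-fold CV on balanced data is systematically below chance
(measured ≈ 45 % here): whenever a class count is not divisible by k, a
training split's class surplus is mirrored by a deficit in its held-out
fold, anti-correlating predictions and test labels. The trimming removes
the bias mechanism; the permutation test's validity is unaffected either
way, since observed and permuted statistics are computed identically.

## Known limitations

- No ocular/muscle artifacts, no volume-conduction forward model, no
  stimulus-locked components (N2/P3), no sequential structure in errors
  (no post-error slowing), no adaptive response-deadline machinery.
- Noise is spatially white; real EEG noise correlations would reduce the
  benefit of averaging neighbouring electrodes.
- Subject-level error rates are fixed per task; empirical per-subject
  error-count ranges are therefore narrower than in typical cohorts.
- Accuracy bands demonstrate internal consistency of the calibrated
  simulator + pipeline, not expected performance on recorded EEG.
- The BrainVision/EEGLAB readers require per-trial metadata and an
  assigned montage, and are exercised only lightly (the internal container
  round-trip is fully tested; writing those binary formats for fixtures
  would require tooling outside this package's dependencies).
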