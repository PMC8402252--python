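# Methods

`gaitclass` is a tested re-implementation of a clinical gait-classification
workflow: 3-D motion-capture joint trajectories are cut into straight-walk
segments, each segment is reduced to six gait features, the feature table
is scaled and class-balanced, embedded into two dimensions by PCA, t-SNE or
UMAP, and classified by ten shallow learners under two cross-validation
schemes. Because no patient recordings are available, the package ships a
synthetic gait generator whose ground truth (contact instants, turn
intervals, drawn step lengths) serves as the oracle for every downstream
stage.

## Synthetic gait model

A walker performs `n_passes` straight passes along a corridor, separated by
2 s turning intervals. Gait is modelled as alternating single-foot swings:
while one foot is planted, the other moves to a landing point one step
length ahead of the most recent foot contact. Per-step advances are drawn
from a Normal(`step_length_mean`, `step_length_sd`²) truncated at zero. The
swing path uses a cosine ease horizontally (zero velocity at take-off and
touchdown), a raised-cosine vertical lift of height `step_height`, and a
lateral circumduction bulge of amplitude `swing_wobble` — also zero at both
ends, so touchdown is soft and analytically instantaneous. The landing
sample index of every swing is recorded as ground truth, as is the drawn
length; the Euclidean distance between consecutive pooled contact
positions equals the drawn length exactly within a pass.

The pelvis — the centre-of-mass proxy — is a one-step moving average of the
feet midpoint, plus a lateral sway sinusoid of amplitude `sway_amplitude`
at step frequency, plus a tremor component band-limited to `tremor_band`
(default [15, 29] Hz, synthesised by drawing complex Gaussian rFFT
coefficients on the in-band bins only, so its spectral confinement is exact
by construction). Turns are modelled as both feet gliding to a parallel
walking line offset 0.5 m while the walk direction reverses; the pelvis
heading consequently rotates 180° over the 2 s interval. A 0.5 s standing
lead-in and tail frame each recording so that initial and final stances are
detectable runs.

### Severity axis

A non-negative severity parameter (0 = healthy archetype) couples
multiplicatively into the kinematics via `EffectSizes`:

| parameter          | healthy default | coupling (at severity *s*) | severity 1.0 |
|--------------------|-----------------|----------------------------|--------------|
| `sway_amplitude`   | 0.02 m          | ×(1 + 2.5·s)               | 0.07 m       |
| `swing_wobble`     | 0.01 m          | ×(1 + 9·s)                 | 0.10 m       |
| `step_length_sd`   | 0.02 m          | ×(1 + 6·s)                 | 0.14 m       |
| `tremor_amplitude` | 0.001 m RMS     | ×(1 + 8·s)                 | 0.009 m      |
| `cadence`          | 110 steps/min   | ×(1 − 0.15·s)              | 93.5         |

These directions mirror what distinguishes cerebellar-ataxic gait
clinically: larger lateral body sway, circumducting and irregular foot
paths, variable step length, high-frequency tremor, slowed cadence. The
magnitudes were fixed once to give a clearly separable cohort at moderate
severity while keeping severity 0.1 nearly null; they are configuration
values, not constants. All-zero effect sizes are the identity, making
ataxic and healthy cohorts statistically indistinguishable (a tested null
case).

Default cohorts use 20 healthy + 23 ataxic walkers (ataxic severities
uniform on [0.25, 1.0]) walking 100 m in 9 passes, which yields ≈387
straight segments — one per pass — matching the few-hundred-segment scale
the pipeline is designed for. Per-recording seeds are spawned
deterministically from a master seed; identical arguments give
bit-identical cohorts.

### What the generator does not emulate

Whole-body dynamics, sensor-fusion artefacts, soft-tissue and footwear
effects, fatigue drift, upper-limb compensation, and inter-subject
anatomical variation. Passing tests therefore demonstrate that the
*pipeline* recovers what the model encodes — not that the classifiers
would reach the same accuracy on clinical recordings.

## Preprocessing

* **Resampling.** 120 Hz recordings are zero-phase FIR low-pass filtered
  (101 taps, 29 Hz cutoff — below the new Nyquist and equal to the highest
  analysed frequency) and decimated by two; 60 Hz input passes through
  unchanged, making the operation idempotent.
* **Turn detection.** The horizontal pelvis track is filtered with a
  zero-phase 2nd-order Butterworth low-pass at 0.5 Hz so that lateral sway
  (≈1.8 Hz) cannot masquerade as heading change; heading is the angle of
  the resulting velocity, and samples with |heading rate| > 45°/s at speed
  ≥ 0.05 m/s are flagged. Flagged runs closer than 1.5 s are merged (the
  heading rate of a single 180° reversal can dip mid-turn under the 0.5 Hz
  filter), runs shorter than 0.3 s are discarded as gait-onset transients,
  and survivors are dilated by 0.5 s per side.
* **Contact detection.** Per foot, positions are smoothed with a zero-phase
  5-sample moving average; stance is flagged where the vertical coordinate
  is below `minimum + 0.1 × range` *and* the speed estimate is below
  0.05 m/s. Because the zero-phase smoothing delays apparent stillness by
  about two samples, the speed signal passes through a forward-looking
  3-sample minimum filter — a sample counts as slow if the estimate drops
  below threshold within the next two samples. Sub-3-sample gaps in a
  stance run are closed, and the first sample of each run is the onset.
  On noise-free cohorts this recovers 100% of ground-truth contacts within
  ±2 samples with no spurious detections outside turns; with 2 mm Gaussian
  position noise, ≥95% within ±3 samples.
* **Segmentation.** The complement of the turn intervals is cut into
  maximal segments; segments keep ≥4 pooled stance onsets (so medians over
  ≥3 steps are meaningful).

## Features

Six numbers per segment: cadence ((pooled contacts − 1)/elapsed time —
interval counting avoids the short-segment bias of event counting); step
length SL (median 3-D distance between adjacent pooled contacts); step
trajectory ST (median arc length of the swinging foot's sampled path
between adjacent contacts); the optimality ratio SL/ST ∈ (0, 1]; COM STD
(SD of the pelvis lateral coordinate after rotating the horizontal track so
forward progress is the first principal axis); and energies of pelvis
acceleration in [3, 15] Hz and [15, 29] Hz. Acceleration is the
second-order central difference of pelvis position per axis (the data model
is positional); each axis's periodogram (Hann window, mean removed — the
window suppresses leakage of the dominant step harmonic into the high band)
is integrated over the band, summed over axes and divided by the segment
length. Energy units are therefore internal to the pipeline; only relative
comparisons are asserted. Note that under the pooled-contact definition the
swing chord spans roughly two step lengths, so healthy SL/ST sits near 0.5
rather than 1; the ratio still falls monotonically with swing tortuosity,
which is what matters for discrimination.

## Scaling and balancing

Min-max rescaling, mean normalisation ((x − mean)/range) and z-score
standardisation (population SD) are implemented as fitted transforms whose
per-feature parameters apply unchanged to held-out rows; a zero-range
column is mapped to zeros with a warning. Class balancing offers majority
subsampling, minority duplication, duplication + Gaussian feature noise
(SD = `noise_scale` × column SD), and SMOTE (synthetic row =
x + u·(x_nn − x), u ~ U(0,1), x_nn among the k = 5 nearest minority
neighbours). Every balanced row carries a provenance flag, and balancing is
applied to training folds only — synthetic copies never reach a test set.
The pipeline default is z-score + SMOTE, recorded in the run config.

## Embedding, classification, validation

PCA (centred, not scaled, full SVD), t-SNE (perplexity 30, PCA
initialisation) and UMAP (15 neighbours, min_dist 0.1) map the scaled
six-feature space to exactly two dimensions. Ten classifiers are
registered: logistic regression; linear, degree-3 polynomial and RBF SVMs;
Gaussian naive Bayes; 5-NN; decision tree; 100-tree random forest; a
one-hidden-layer (100-unit) MLP; and 50-stump AdaBoost. A quadratic
discriminant is available in the registry but excluded from the default
grid. All stochastic learners take derived per-cell seeds, so a full grid
rerun is bit-identical.

Validation is either a stratified 60/40 holdout or leave-one-group-out with
the participant as group (no subject appears in both train and test).
Because t-SNE has no out-of-sample transform, two modes exist: **joint**
(default) fits scaler and reducer on all segments before splitting —
replicating the common visual-embedding workflow but leaking test
information into the embedding, which every report flags — and **strict**
fits them on training rows only, placing t-SNE test points at the
inverse-distance-weighted average of their five nearest training points'
embedding coordinates. Metrics are pooled over test predictions (not
averaged per fold — robust to unequal LOGO fold sizes); sensitivity is
recall on the ataxic class, specificity recall on the healthy class.

## Severity separation

To make "the embedding separates subjects by severity" testable, two
statistics are computed on a 2-D embedding: Spearman rank correlation
between per-segment severity and the projection onto the least-squares
severity-discriminant direction of the standardized coordinates, and the
ratio of mean between-tertile to mean within-tertile pairwise distance
(>1 means graded groups occupy distinct regions). Both per-segment values
are reported; shuffled severities drive the correlation into the null band.

## Numerical choices and degenerate inputs

Contact ties at the standing start (both feet at the origin) are kept and
pooled deterministically (left before right); stationary recordings raise
"no gait detected" rather than returning fabricated events; recordings too
short to filter return no turns; segments shorter than 1 s refuse spectral
estimates; SL > ST beyond 1e-9 raises instead of clipping; constant feature
columns scale to zeros with a warning; perplexity is capped at (n−1)/3 for
small tables; cell failures inside the evaluation grid are flagged in place
and never abort the remaining cells. All randomness flows from explicit
seeds through `numpy.random.Generator`/`SeedSequence`.

## Problem sizes

Default experiment sizes were chosen once for desk-scale runs: 43-walker
cohorts (≈387 segments) for grid experiments, 10-recording cohorts for
detection oracles, and an 16-walker, 5-pass configuration for the
end-to-end determinism check. The full test suite and the acceptance
script each complete in about a minute on one CPU.

## Known limitations

The generator's step timing is metronomic within a recording (cadence
varies only across severity); real ataxic gait shows cycle-to-cycle timing
variance. Turn kinematics are stylised (feet glide, no pivot steps), so
turn-detection margins on real data will be narrower. The six features are
the only inputs; the many other literature gait descriptors (symmetry,
smoothness, regularity indices) are out of scope. Accuracies measured on
synthetic cohorts characterise the pipeline, not clinical performance.
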