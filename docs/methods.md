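# Methods

`aggrebout` re-implements, as a tested and reusable pipeline, the
computational path from raw behavioral recordings to statistical
conclusions used in longitudinal aggression studies of
senescence-accelerated (SAMP8) versus senescence-resistant (SAMR1)
mice: machine scoring of attack bouts in resident–intruder (R-I)
sessions, three-chamber sociability readouts from tracked trajectories,
and the statistics applied to the resulting per-animal tables.  Because
no raw recordings are published for this kind of study, a synthetic-data
layer generates all inputs with the statistical structure the analysis
assumes, and the whole chain is validated end-to-end against that
ground truth.

## Pose-free aggression scoring

### Input representation

Frames are converted to grayscale (ITU-R BT.601 luma weights 0.299,
0.587, 0.114 — any fixed convention works; this is the 8-bit video
standard).  The classifier input replaces the three color channels with
temporal structure: channel 0 is the current grayscale frame, and each
further channel is the signed difference between the current frame and
a lagged previous frame.  Default lags are (1, 2), filling a 3-channel
input; frames earlier than a lag get a zero difference channel.  A
static scene therefore produces all-zero motion channels and the
tussling motion of an attack appears directly as input signal, which is
what lets a small network detect fighting without pose estimation.

### Classifier

A small convolutional network: three 3×3 same-padding conv blocks
(8 → 16 → 32 filters, ReLU, 2×2 max-pool), global average pooling, and
one logistic output unit.  The network is implemented directly on
numpy (im2col-lowered convolutions, analytic backprop verified against
finite differences in the test suite) and trained with Adam
(lr 3·10⁻³, batch 32, 12 epochs by default) on a class-weighted binary
cross-entropy.  Inputs are normalized per channel to [−1, 1] by the
training-set maximum absolute value, which is stored in the model so
inference is exactly reproducible; models serialize to a metadata JSON
plus a weights archive and reload bit-identically.

Attack frames are rare — about 1% of a session — so training balances
classes twice: negatives are subsampled per video (default 8 negatives
per positive; videos without any bout contribute a fixed background
sample of 120 frames), and the remaining imbalance is absorbed by a
positive-class loss weight (negatives/positives of the assembled set).
Training on every negative frame instead would cost ~10× the CPU time
for no measurable accuracy gain on separable synthetic data.

### Validation and operating point

Validation is leave-one-video-out: each labeled video is held out once
and frame-level ROC AUC (Mann–Whitney formulation, ties ½) is computed
on every frame of the held-out video.  A held-out video that contains
no bout (common at 1% prevalence and short sessions) has no defined
frame-level AUC; such folds report `auc = None` and are excluded from
the mean.  The operating threshold is chosen specificity-first: the
smallest threshold achieving a specificity floor (default 0.99) on
labeled data, maximizing sensitivity subject to that floor.  With 99%
of frames negative, even a small false-positive rate would otherwise
dominate the scored attack duration; the cost is reduced sensitivity,
i.e. a systematic underestimate of attack time, which is the accepted
trade-off for this assay.

### Event bounding

Per-frame probabilities are smoothed with a centered moving average
(default 5 frames; the window shrinks at the edges), frames strictly
above the threshold form candidate events, candidates separated by at
most `merge_gap` frames (default 0.5 s) are merged, and merged events
shorter than `min_duration` (default 0.3 s) are discarded.  Merging
precedes the duration filter so a bout fragmented by a brief
probability dip is not discarded piecewise.  Intervals are 0-based and
closed, so duration is exactly (end − start + 1)/fps, and the session
score is the cumulative attack duration over the 10-min test.
Event-level evaluation uses greedy one-to-one matching in temporal
order with a configurable intersection-over-truth floor (default 50%).

## Three-chamber test readouts

The tracker exports nose, body center and tail base in cm.  Stimulus
exploration is the time the nose spends within 2.5 cm of a cylinder
wall, i.e. nose-to-center distance ≤ cylinder radius (5 cm) + 2.5 cm,
boundary inclusive.  The margin is measured from the wall, not the
center: a 2.5 cm radius about the center would lie inside the 5 cm
cylinder and be unreachable.  The proximity zone is modeled as circular.
Each sample carries one inter-sample interval of dwell (its following
interval; the last sample inherits the preceding one), so a uniformly
sampled park of n samples at rate f scores exactly n/f seconds.
Locomotion is the summed Euclidean path length of the body center.
NaN tracking dropouts contribute neither dwell nor path segments; no
interpolation is invented.  Per-phase summaries resolve the two
physical cylinders into stimulus identities (object vs stimulus mouse;
familiar vs unfamiliar) through the counterbalanced side assignment;
relabeling never changes the per-cylinder times.

## Statistics

Attack durations are heavy-tailed with occasional exact zeros (sessions
without any attack), so analyses run on log-transformed values.  When
zeros are present the transform adds a constant c = √(Q1/Q3) computed
on the full value set (quartiles by linear interpolation).  The phrase
defining this constant admits a second parse, √Q1 / Q3; the ratio
reading was chosen because it is dimensionless and therefore invariant
to the measurement unit, and the constant used is always reported in
the output.  If Q1 is itself zero the fallback is half the smallest
positive value, with a warning.  Natural log is used; the base cannot
affect any t or F statistic.

Group contrasts use Welch's unequal-variance t-test, two-sided, with
Welch–Satterthwaite degrees of freedom, computable from raw data or
from published summary statistics (mean, SD, n) — the two agree exactly
when the summaries come from the same raw data.  Note that published
summaries are themselves rounded, so t-values recomputed from a printed
table can differ from the original full-precision value in the last
digit.

The drug cross-over design (between-subject factor genotype,
within-subject factor treatment) is analyzed with a classical
split-plot decomposition: genotype is tested against
subjects-within-genotype, treatment and the interaction against the
subject × treatment residual.  Subjects missing a within-subject level
are dropped (complete-case) and counted in the output; the
decomposition handles unequal group sizes.  With a two-level within
factor sphericity corrections are moot.  Tukey HSD runs over the four
genotype × treatment cell means using the studentized-range
distribution with k = number of cells; following split-plot practice,
comparisons that differ in treatment use the within-subject residual
MS, while comparisons differing only in genotype use the
between-subject error MS.  The Sidak adjustment
p_adj = 1 − (1 − p)^m is provided for planned comparisons.  α = 0.05,
two-sided, throughout.

## Synthetic data

The generator layer defines the study conditions under which the
pipeline is validated.

**R-I videos.** Two Gaussian-edged discs — a light resident (level
220), a dark intruder (level 40) on a mid-grey background (128) — walk
with reflecting boundaries in a 64×64 px frame at 15 fps, with additive
Gaussian pixel noise (SD 3).  Attack bouts arrive as a Poisson process
(default 0.25 bouts/min, duration uniform 1.5–3.5 s) thinned so bouts
never overlap; during a bout the intruder is projected to within the
contact distance (10 px) of the resident every frame and both centers
receive high-frequency jitter (SD 3 px/frame) on top of a reduced walk.
Outside bouts a soft mutual repulsion keeps chance near-contacts rare.
The defaults put attack-frame prevalence near 1%, the rare-event regime
reported for real recordings, which is what makes the class-imbalance
machinery worth testing.  Ground-truth labels are frame-level (a frame
is aggressive iff inside a bout) and the contact constraint holds
exactly on every labeled frame.  What the generator does not model:
fur texture, occlusions, shadows, non-attack social contact, and
non-contact aggressive displays (lateral threats, offensive uprights)
— so passing tests demonstrate the machinery recovers its own ground
truth under realistic prevalence and geometry, not performance on real
videos.

**Three-chamber trajectories.** The body center follows a persistent
random walk (speed default 6 cm/s, giving ≈3500 cm per 10-min phase,
the magnitude of real locomotion) in the 40.5 × 60 cm arena with a
cylinder (radius 5 cm) centered in each lateral third.  Exploration is
bout-structured, as in real sessions: the walk alternates free roaming
(8 s) with 12-s seek excursions during which a bias pulls it toward one
cylinder.  Excursion targets are stride-scheduled — the cylinder with
the largest weighted dwell deficit is chosen next — so long-run dwell
near each cylinder tracks the preference weights without the visit-count
noise (or the metastable sticking) that a static summed bias field
produces.  Equal weights give symmetric dwell; a (3, 1) preference
yields roughly 3× the dwell at the preferred cylinder.  Nose and tail
base are placed 3 cm ahead of / 4 cm behind the body center along the
heading.

**Cohort tables.** One row per animal × age × session with attack
duration generated as exp of a normal linear model on the log scale:
baseline log 3.0 (≈20 s), between-subject SD 0.6, residual SD 0.5, a
genotype effect (+0.8) for the prone line from the onset age (5 months)
onward, a treatment effect (−1.0) under drug at the final age
(cross-over: vehicle and drug sessions per animal), durations clamped
to [0, 600] s, and exact zeros injected with probability 0.15 —
the feature that motivates the zero-safe transform.  Effect sizes are
not fitted to any published data; they are chosen once as plausible for
this assay and are fully configurable.

## Numerical and design choices

- Event thresholding is strict (> θ) for deterministic tie behavior;
  interval endpoints inclusive.
- Specificity floor 0 is allowed and returns a threshold below the
  minimum score (everything called positive).
- ROC AUC uses midranks, so it is invariant under strictly monotone
  score transforms and handles ties exactly.
- All generators and training runs are pure functions of (parameters,
  seed); the pipeline fans one global seed out to stages by fixed
  offsets.
- Degenerate ANOVA inputs (zero residual variance) yield inf/nan F
  rather than an exception; tiny negative sums of squares from
  cancellation are clamped to zero.

## Problem sizes used in validation

The validation suite trains leave-one-video-out on eight 2-min 64×64
sessions (the acceptance script recomputes exactly this), checks
end-to-end duration recovery on two held-out 10-min sessions at 0.6
bouts/min (the default ~1%-prevalence rate would put only ~2 bouts in a
10-min session, making a relative ±20% criterion a test of Poisson
noise rather than of the chain), and calibrates null rejection rates
over 2000 simulated cohorts.  Unit tests use smaller frames (32×32)
and shorter sessions with denser bouts.

## Known limitations

- The classifier is validated only on synthetic footage; real videos
  add texture, lighting drift and identity ambiguity it has never seen.
- The split-plot ANOVA assumes compound symmetry (automatic with two
  within levels) and complete cases; it does not fit mixed models with
  partially missing within-subject data.
- Tukey comparisons that differ in both factors use the within-subject
  residual error term, a common but approximate split-plot convention.
- Event matching is greedy one-to-one in temporal order; pathological
  fragmentations could match differently under optimal assignment.
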