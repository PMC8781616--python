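# Methods

This note documents the models, numerical choices and limitations of the
package in enough detail to reproduce or audit any stage.

## Signal model and featuring chain

The input is a uniformly sampled single-channel voltage series (default
360 Hz).  Analysis frames are 3 s (1080 samples), half-open `[start, end)`
windows; frames cut around an annotated interest point are **centered** on
its timestamp and shifted inward at record edges rather than truncated, so
the symptomatic waveform stays whole.  Whether the original labelling
convention centered frames or started them at the interest point is not
determinable from the available description; centering is this package's
choice and is applied consistently to training and scanning.

### Filtering

A 5th-order low-pass Butterworth filter with 16 Hz cutoff removes mains and
muscle noise while preserving PQRST morphology.  It is applied
forward–backward (`scipy.signal.sosfiltfilt`), i.e. zero-phase: beat
positions do not shift, at the cost of squaring the magnitude response (gain
0.5 rather than 0.71 at the cutoff).  DC gain is exactly 1.  The phase
handling is this package's choice; one-pass filtering would shift wave
positions by several samples and distort the mode decomposition near the
QRS complexes.

### Empirical mode decomposition

Sifting subtracts the mean of the upper and lower cubic-spline envelopes
through the local maxima/minima.  Numerical choices, all of which matter near
the frame boundaries:

* **Extrema detection** uses strict sign changes of the first difference;
  plateau interiors inherit the preceding slope so a flat top counts as one
  extremum.
* **Boundary handling**: the two end extrema on each side are mirrored
  beyond the frame edge before spline fitting.  Without this, envelope
  splines diverge at the edges and corrupt the first mode.
* **Stop rule per mode**: the Cauchy criterion
  `Σ(h_prev − h)² / Σ h_prev² < 0.2` (the classical sifting default),
  accepted only once the candidate also satisfies the mode condition
  |#extrema − #zero-crossings| ≤ 1, with a hard cap of 100 sifts.
* **Termination**: decomposition stops when the residue has fewer than two
  maxima or two minima (monotonic in the broad sense) or after 10 modes.

Completeness — modes plus residue reproducing the input to better than 1e−8
relative — holds by construction and is asserted over random frames in the
test suite.

### Hilbert spectral analysis

Each mode's analytic signal (`scipy.signal.hilbert`) yields the amplitude
envelope and the instantaneous frequency as the central-difference derivative
of the unwrapped phase.  Negative instantaneous frequencies (numerical
artifacts near low-amplitude regions) are clipped to 0; the first and last 2%
of samples are excluded from spectral accumulation to suppress end effects.
Both choices are stabilization details, not physics.

The marginal spectrum accumulates `a(t)·Δt` per frequency bin on a 0–20 Hz
grid at 0.05 Hz resolution (signals are band-limited to 16 Hz; observed
centroids all sit below 8 Hz).  Frequencies beyond the grid are clipped into
the edge bins, which makes the bin sum conserve the time-integrated energy
exactly.  An `energy="squared"` switch accumulates `a²(t)·Δt` instead; the
default is amplitude-based.  The centroid is the energy-weighted mean
frequency together with total energy divided by frame duration ("power").
The alternative reading of an *area* centroid — the geometric centroid of the
region under MHS(ω), whose y-coordinate is half the mean curve height — is
deliberately not used: the energy-per-second definition matches the stated
meaning of the power feature.  An all-zero spectrum maps to the defined
degenerate centroid (0, 0).

Frames that decompose into fewer than three modes report missing centroids
as (0, 0) and carry a `"padded_imfs"` warning flag.

## Synthetic data

### Gaussian feature simulator

`reference_feature_model()` carries the published per-class mean and standard
deviation of the six features, measured on ~4,200 frames of annotated
arrhythmia records.  `simulate_features` draws each feature independently
from its class-conditional normal; the published table gives no covariances,
so none are modelled — a documented limitation, since the real features are
correlated across modes.  Negative draws are clipped to zero (frequencies and
powers are physical); clipping is logged and can be disabled for
moment-fidelity checks.  For heavy-tailed cells (VT power: σ ≈ μ) truncation
noticeably raises the sample mean, which is why raw-moment checks disable it.

### Waveform generator

`simulate_ecg` builds beat trains from a Gaussian-bump PQRST template with
per-class modifications: NSR has regular RR (cv < 0.05) with P waves; APC
inserts early narrow beats followed by compensatory pauses (premature
fraction 0.25); AFib draws RR from a uniform ±40% window (cv > 0.15),
suppresses P waves and adds a ~6 Hz wandering fibrillatory baseline; VPC
inserts early wide (2.5× QRS width), large (1.5×) beats; VT is a sustained
run of wide beats at 160 bpm.  A 0.01 mV white-noise floor is added.
Annotations mark every beat for NSR/AFib/VT and the ectopic beats for
APC/VPC.

These fixtures are openly synthetic.  They reproduce the *ordering* of the
real feature distributions (normal rhythm: highest IMF1 frequency, lowest
power) and give a class separation the end-to-end tests quantify (NSR vs VT
IMF1-power means more than one pooled SD apart), but they do not emulate real
morphological variability, baseline wander, electrode noise or mixed rhythms.
Passing tests therefore demonstrate pipeline correctness and internal
consistency, not clinical performance.

## Classifier bank

All four methods sit behind one train/predict surface with one-versus-one
coding implemented in-package: one binary learner per unordered class pair,
pairwise posteriors summed per class and normalized to a score vector summing
to 1; ties break toward the lower symptom ID.  The binary learners are
scikit-learn estimators:

* **MLP** — one hidden layer of 10 units, cross-entropy loss, adam to
  tolerance 1e−6 or 500 epochs with early stopping on a 20% validation
  split.  The learning rate (0.01) and patience (50 epochs) are raised from
  scikit-learn defaults because the training sets here are small (tens to
  hundreds of records per pair) and the default patience stops training near
  the random initialization.
* **Boosted ensemble ("rf")** — AdaBoost over decision trees with at most 10
  leaf nodes, 100 learning cycles.  The method keeps the conventional "rf"
  name while the default aggregation is boosting, matching its reference
  parameterization; `rf_aggregation="bag"` switches to a true bagging random
  forest with the same tree-size cap.
* **SVM** — linear kernel by default (RBF selectable; for RBF the kernel
  scale s enters as gamma = 1/s²), margins calibrated to posteriors by
  sigmoid (Platt) calibration on internal cross-validation.
* **NB** — Gaussian class-conditional densities per feature (scikit-learn's
  default variance regularization, 1e−9 of the largest feature variance).

Features are z-scored with training-set statistics before the MLP and SVM —
a unit kernel scale is only meaningful on standardized inputs — and left raw
for trees and NB, which are scale-equivariant.  Scaling parameters are stored
in the model bundle so prediction is self-contained.  Training requires at
least two classes and five records per class.  Everything is deterministic
under a fixed config seed (per-pair seeds are derived arithmetically).
No class reweighting is applied by default — balance is expected to come
from the data design — with `class_weight="balanced"` available.

Model bundles are joblib files carrying a format version, the config, the
scaling parameters, the learners and per-class training counts; loading
rejects unknown versions and unreadable files explicitly.

## Evaluation

Confusion metrics follow the standard definitions; a zero denominator yields
an explicit `undefined` flag rather than NaN.  ROC curves enumerate all score
thresholds (`drop_intermediate=False`), AUC is the trapezoid area, and the
reported operating point maximizes Youden's J (first such threshold when
tied) — the threshold rule is this package's choice.  Pattern evaluation
trains one multiclass model per method and scores: each unordered symptom
pair on the test records of those two classes, with the higher symptom ID as
the positive class and score `s_b/(s_a+s_b)`; and each one-versus-rest class
on the full test set with its own score column.  Cross-validation is
stratified k-fold (default 5, i.e. 80%/20%); records are pre-sorted by
(label, feature values) so fold assignment is invariant to input order, and
per-class fold sizes differ by at most one.

The pairwise feature-significance test defaults to Welch's t (unequal
variances) with Mann–Whitney U as an option; the published per-pair p-values
were produced by an unspecified test on the original per-frame data and are
not recoverable from summary statistics, so they are not a verification
target here.  No multiple-testing correction is applied.

## Scanning

A record is tiled with 3-s frames overlapping by 1 s (step 2 s; a 30-s
segment yields 14 frames) and each frame is labelled independently; an
optional majority-vote smoother over adjacent frames exists but is off by
default, because independent per-frame labels are the traceable output the
design calls for.  Every scan result embeds the full pipeline-config
snapshot for audit, and the exported track CSV round-trips exactly.

## Problem sizes in tests and the acceptance script

The test suite exercises EMD correctness on 100 random frames, generator
moments at 100,000 draws per cell, classifier contracts on 200–5,000-record
feature sets, and end-to-end recovery over 10 seeds with one 30-s training
record pair and one fresh record per class per seed — sizes chosen so the
whole suite completes in well under a minute per module while keeping every
statistical margin wide (moment checks at 4 standard errors, recovery
thresholds at 70% against empirically near-perfect separation).  The
acceptance script runs only the feature-space generator and finishes in
seconds.

## Known limitations

* Feature draws are independent across dimensions; real centroid features
  are correlated.
* The waveform generator is a caricature of each rhythm, adequate for
  separability testing only.
* Published end-to-end recognition tables for real annotated records are not
  reproducible here without that data and its manual screening; the package
  verifies its machinery on self-contained and synthetic inputs instead.
* EMD mode mixing (one physical oscillation split across modes) is not
  mitigated; ensemble EMD is out of scope.
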