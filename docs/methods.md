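# Methods

## Problem and data model

The package classifies fixed-length segments of waist-worn IMU data
(tri-axial accelerometer in g, tri-axial gyroscope in deg/s, 200 Hz) into
ten classes: four activities of daily living (walking W, jogging J,
sitting S, standing SB) and six fall classes crossing direction
(forward/backward/lateral) with severity (hard = direct impact, soft =
impact dampened by support): FHF, BHF, LHF, FSF, BSF, LSF. A second label
scheme pools the four ADLs into a single class, giving a 7-class
falls-vs-ADL problem. The label table maps SisFall activity codes to these
classes; codes outside the table (e.g. car entry/exit protocols) are
excluded from the problem rather than treated as errors, so a full dataset
directory can be swept.

Raw files carry ADC counts. Conversion to physical units is linear,
`value = counts · 2·range / 2^bits`, with the full-scale constants held in
`SensorConfig` (defaults: ±16 g / 13-bit accelerometer, ±2000 deg/s /
16-bit gyroscope). Which of the unit's two accelerometers is used is
configurable (default: the first/wide-range one). Window placement depends
only on the *argmax* of the acceleration magnitude, which is invariant to
any positive per-channel scaling, so the choice of conversion constants
cannot move windows.

## Windowing

For every sample j the signal magnitude vector
`SMV_j = sqrt(A_xj² + A_yj² + A_zj²)` is computed over the three
acceleration channels. Transient activities and falls yield one window of
L = duration·fs samples (600 at the 3 s / 200 Hz defaults) centred on the
SMV argmax; ties break to the earliest index for determinism. Because L is
even the peak cannot be exactly central: it sits at offset L/2 (300
samples precede it). If the nominal span `[p − L/2, p + L/2)` crosses a
recording boundary it is shifted minimally to fit — clamping rather than
zero-padding, so no fabricated samples enter the learned feature
extractor. Recordings shorter than L raise an error rather than being
padded; real SisFall recordings (≥ 12 s) never trigger this.

The long 100 s continuous walking/jogging protocols (codes D01–D04) use
non-overlapping consecutive windows instead, discarding the trailing
remainder — these activities are stationary in character and have few
trials, so slicing the whole recording yields the needed sample count.

## Augmentation

Minority classes — standing plus all six fall classes — get exactly three
variants per original training window:

* **noise**: iid zero-mean Gaussian, σ = 0.01 in converted units (the
  same scalar is used for both modalities since the magnitude is an
  emulation of measurement noise, not a calibrated sensor model);
* **scale**: one scalar u ~ Uniform(0.8, 1.2) multiplying the whole
  window — a single factor preserves inter-axis geometry, consistent with
  its physical motivation (sensor fixation / physique differences);
* **resample**: upsample ×10 by linear interpolation, decimate by stride
  back to L samples. Linear interpolation is the minimal reading of
  "resampling after interpolation"; decimation is a plain stride, not an
  anti-aliased decimator (the alternative is noted as a possible variant).
  The operation is deterministic, so only the noise and scale variants
  depend on the augmentation seed.

Augmentation applies to the training split only; validation and test
windows are never augmented.

## Model

Feature extractor: four 1D conv layers of 64 filters, kernel length 3,
valid convolution, stride 1; each conv is followed by batch normalisation
then ReLU (BN before activation); average pooling of length/stride 2
follows conv layers 1–3 only. For L = 600 the temporal lengths are
598 → 299 → 297 → 148 → 146 → 73 → 71, so the flattened feature vector has
71 · 64 = 4544 dimensions — asserted in tests against this closed form.
The network consumes raw converted measurements; no input standardisation
is applied beyond the network's own batch norm layers.

The stack is implemented directly on NumPy (`fallwatch.nn`) with explicit
backpropagation; analytic gradients are verified against central finite
differences in the test suite. Training: categorical cross-entropy via a
temporary fully connected softmax head, plain SGD with learning rate 0.01
and batch size 20, shuffled batches (a trailing batch of size 1 is skipped
because batch norm is undefined there). After each epoch the validation
UAR is recorded; the returned model is the parameter state (including BN
running statistics) with the highest validation UAR. Training stops after
`patience` epochs without improvement (patience 0 therefore trains exactly
one epoch) or at `max_epochs` (defaults 20 / 200 — chosen so early
stopping, not the cap, normally ends training).

Head swap: features are extracted in inference mode (BN running
statistics), so they are bitwise-independent of the softmax head. An
XGBoost classifier (`tree_method="hist"`) is grid-searched over tree count
× depth × learning rate ({100, 300, 500} × {3, 6, 9} × {0.05, 0.1, 0.3}
by default), each candidate fitted on training features and scored by
validation UAR, ties broken toward fewer trees then shallower depth. No
class reweighting is applied at this stage — augmentation already
addresses imbalance. Class labels are encoded to a contiguous range
internally so the head also works when only a subset of classes is
present.

Splits are stratified per class (70/15/15 by default, configurable),
deterministic given the split seed; every class needs at least three
windows, and rounding never leaves a class absent from a split.

## Evaluation

All metrics derive from the test-split confusion matrix. Per class
(one-vs-rest): recall = TP/(TP+FN), precision = TP/(TP+FP), specificity =
TN/(TN+FP), F1 — as percentages. Zero-denominator cells report 0 with a
logged warning so macro averages stay defined on degenerate splits. UAR is
the plain arithmetic mean of the k per-class recalls — one term per class,
which is the reading consistent with the benchmark tables this package
reproduces in its acceptance checks. Roll-ups are unweighted means of
constituent fall-class recalls: direction pools the two severities
(forward = mean recall of FHF, FSF; similarly backward, lateral), severity
pools the three directions (hard = mean of BHF, FHF, LHF; soft
analogous), and the falls-only average covers all six. Since hard and soft
partition the six classes 3+3, the mean of the two severity UARs equals
the falls-only average. Rendered reports round half-up to two decimals;
internal values are never pre-rounded.

## Synthetic data generator

The generator emulates the SisFall file layout (directory per subject,
`<code>_<subject>_R<NN>.txt`, nine integer columns), sampling rate, trial
counts (one trial for D01–D04, five elsewhere), and the qualitative signal
character of each class, with all randomness derived from
(seed, code, subject, trial) so every file is individually reproducible:

* baseline 1 g gravity on the z-axis plus Gaussian floor noise
  (σ = 0.02 g accelerometer, 1 deg/s gyroscope), quantised to ADC counts
  by inverting the unit conversion (round-trip error ≤ 1 LSB, tested);
* walking/jogging: sinusoidal gait at ~1.8 Hz / 0.35 g vs ~2.6 Hz /
  0.9 g with correlated gyroscope oscillation, per-recording jitter of
  ±10–15 % in frequency and amplitude;
* sitting: one sigmoid postural transition with a ≤ 1.2 g bump and
  partial gravity reorientation;
* standing: low-amplitude sway (0.02 g);
* falls: exactly one Gaussian impact transient at a uniformly random
  interior instant at least L/2 samples from both ends (so the peak
  window never needs clamping — the clamping branch is tested with
  purpose-built fixtures instead). Direction sets the impact axis and
  sign (forward +x, backward −x, lateral +y); severity sets the peak
  (hard 6 g, soft 3 g) and the gyroscope transient (250 vs 120 deg/s);
  soft falls add a 1.5 g "support" bump 0.5 s before impact; afterwards
  gravity reorients onto the impact axis (lying posture).

A configuration invariant enforces hard peak > soft peak > every ADL
amplitude, which guarantees the impact dominates the SMV and the
peak-centred window contains it. The default dataset is two subjects with
the protocol trial counts (≈ 520 windows; the rarest fall classes, BHF and
LHF, contribute 10 windows each because a single protocol code feeds
them).

What passing on this data shows — and does not. The classes are separable
by construction (distinct axes, amplitudes, and frequencies), so a
high test UAR demonstrates that windowing, augmentation, training, the
head swap, and evaluation are wired correctly end to end; it says nothing
about accuracy on real human kinematics, inter-subject variability, sensor
drift, or elderly-vs-adult differences, none of which are modelled.

## Scaled-down reference run

`fallwatch.experiments.scaled_synthetic_run` fixes the problem size used
by the acceptance checks: the default two-subject synthetic dataset,
training capped at 30 epochs with patience 6, and a 4-point XGB grid
({100, 300} × {3, 6} × {0.3}). These sizes complete the whole experiment
in a few minutes on one CPU core while still exercising every stage; the
full 27-point grid and 200-epoch cap remain the library defaults.

## Numerical and design notes

* Window tie-breaks, split allocation, and grid-search tie-breaks are all
  deterministic; one global seed derives every stage seed.
* The CNN uses float32; gradient checks run at small sizes in float32
  against float64 finite differences with tolerances of 1e-2 relative.
* Pooling floors odd lengths (one trailing sample dropped), matching the
  shape arithmetic above.
* The conv/pool geometry, padding, split fractions, epochs/patience, and
  XGB grids are artefact choices exposed in configuration, not fixed
  facts of the protocol; the windowing, augmentation, and optimiser
  constants are the protocol and appear annotated in the default YAML.

## Known limitations

* No overlapping windows, pre/post-impact phase segmentation, or adaptive
  window lengths.
* The generator's second accelerometer duplicates the first through the
  same ADC rather than modelling a distinct sensor position.
* XGBoost may exploit multiple cores if available; results are unaffected
  but timings vary.
* Real-data performance requires downloading SisFall; the package reads
  it directly but ships no copy of it.
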