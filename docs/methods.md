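# Methods

This note documents the models, conventions and numerical choices behind
`emgfi`, in the order the pipeline runs them.

## Signal model and acquisition geometry

The data model is a 3×16 intra-anal electrode array: three rings of 16
silver bar electrodes (1×9 mm, 8 mm between rings) at depths 0–9, 18–27 and
35–44 mm from the anal verge, ring 1 closest to the anus. A session records
the external anal sphincter at each ring in the relaxed (R) and maximally
contracted (C) state, twice, as 10-s epochs sampled at 2048 Hz in the
10–500 Hz (−3 dB) band.

Amplitudes are millivolts end to end. The acquisition hardware's ADC gain is
not published for this probe family, so mV is a documented convention, not a
calibration: all thresholds that depend on absolute level (simulator anchors,
QC contact-loss floor) are expressed relative to in-recording statistics or
are configurable.

Epochs are persisted one per EDF file (ASCII header, int16 records, physical
dimension mV, channel labels `R<ring>E<electrode>`), with a JSON manifest
binding a subject's 12 epochs. The physical range is set per file to the data
extremes and rounded upward in the 7-character EDF bound field, so
quantization error is at most one digital step of ~`2·peak/65535` and no
sample is ever clipped. Reading is delegated to MNE; a sample-rate or
channel-label mismatch is a hard error — the package never resamples.

## Feature extraction

Per epoch:

1. **Bipolar derivation.** Pair *k* = electrode *k* − electrode
   *k* mod 16 + 1, a circumferential single-differential montage with
   wrap-around. It is the only pairing that yields exactly 16 pairs per ring,
   and it cancels the ring's common-mode (common-drive) component; the 16
   pair traces telescope to zero at every sample, which the tests exploit.
2. **Band-limiting.** 4th-order Butterworth 10–500 Hz applied
   forward-backward (`sosfiltfilt`), i.e. zero phase. Traces shorter than
   three settling lengths (3 × one period of the 10 Hz cutoff ≈ 0.3 s) are
   rejected.
3. **RMS.** √(Σaᵢ²/n) per pair, in mV.
4. **Median frequency.** Welch PSD (Hann window, 1-s segments, 50 % overlap,
   density scaling) and the smallest frequency at which the cumulative
   in-band (10–500 Hz) power reaches half the total, linearly interpolated
   inside the crossing bin. A pure tone therefore lands within half a 1-Hz
   bin of its true frequency.

The 12-parameter vector (RMS1R…RMS3C in mV, MF1R…MF3C in Hz) averages each
quantity over the 16 pairs of a ring, then over the two repetitions. Whether
the original analysis computed MF per pair and averaged, or on a
ring-averaged signal, is not published; the per-pair choice mirrors the RMS
averaging and is symmetric in the two modalities, which is why it was
adopted. Because averaging over pairs is invariant to a rotation of the
ring's electrode labels, so is the feature vector.

## Quality control

Clinical multichannel sEMG is excluded, not repaired, when artifacts
dominate; the screening mirrors that practice with three per-channel
detectors, all thresholds configurable (`QCConfig`):

| detector        | rule (defaults)                                                       |
|-----------------|-----------------------------------------------------------------------|
| contact loss    | channel RMS < 1 % of the epoch's median channel RMS, or > 1 % of samples at the epoch's amplitude extreme |
| mains           | > 25 % of band-passed power in 49–51 Hz                               |
| movement burst  | any 0.5-s window RMS > 6× the channel's median window RMS             |

An epoch is unreliable when more than 4 of its 16 channels carry any flag;
any unreliable epoch rejects the whole session, with the per-epoch reports
attached to the exception. The "more than 4" cutoff operationalises
"several of the 36 recording electrodes" failing; it is a surrogate, not a
published constant, and is the single most influential QC parameter.

## Classification trees

The CART engine is self-contained and deterministic:

* **Impurity** Gini, empirical priors, unit misclassification costs
  (a 4×4 cost matrix is accepted where costs are weighted).
* **Candidates** midpoints between consecutive distinct sorted values of
  each of the 12 features; ties on impurity decrease break to the lowest
  feature index, then the lowest threshold.
* **Stopping** `min_split=5`, `min_leaf=1`, `max_depth=10` — defaults sized
  for a ~100-subject cohort where deeper trees only memorise.
* **Pruning** minimal cost-complexity (weakest-link): breakpoints
  g(t) = (R(t) − R(T_t)) / (|T_t| − 1), collapsing every minimiser and
  re-computing until the root leaf; zero-gain links are collapsed at α = 0.
  The resulting sequence is validated to have strictly increasing α,
  non-increasing size and non-decreasing resubstitution cost.
* **Cross-validation** V = 10 folds, stratified by class via seeded
  round-robin dealing. Stratification here is proportional allocation: with
  a class of 6 subjects and V = 10, some folds simply contain none — the
  same regime as the original 98-subject analysis. Each pruning interval is
  scored at the geometric mean of its endpoints by growing and pruning a
  tree per fold; the CV cost pools all held-out errors and its standard
  error is binomial, √(c(1−c)/n).
* **Selection policies**, mapping to the three published tree variants:
  `min_cost` (minimal CV cost, ties to the smaller tree), `min_nodes`
  (smallest subtree within a configurable absolute CV-cost ceiling, default
  0.10, above the minimum), and `balanced` (the 1-SE rule). The 1-SE rule is
  this package's operationalisation of "cost and size considered jointly";
  the original software's criterion is not published.
* **Conventions** `feature ≤ threshold` routes left; leaf majority ties
  break in the fixed class order control < neurogenic < myogenic <
  idiopathic. Both are stamped into every JSON export.

Raw patient recordings for the original cohort are not available, so the
published trees' split thresholds cannot be re-derived; what the engine
reproduces is the tree algebra (strict binary shape, prune-path optimality
— both checked against exhaustive enumeration in the tests) and the
performance arithmetic below.

## Evaluation

Confusion matrices are rows = observed, columns = foreseen, in canonical
class order. Sensitivity is diagonal/row-total; specificity is one-vs-rest
over all non-class subjects, controls included. The bundled reference counts
from the original cohort reproduce every derivable printed figure (row
percentages to two decimals, overall accuracy to one, costs as integers —
one central rounding routine). The reference report's printed specificities
are not derivable from its own printed counts under either one-vs-rest or
an FI-only definition; this package documents its definition and does not
chase those four numbers.

## Simulator

**Raw level.** An epoch channel is Gaussian noise spectrally shaped to a
flat band of width 120 Hz centred on the target MF (shrunk to stay inside
10–500 Hz) and rescaled to the exact target RMS, plus a per-ring
common-drive trace carrying 30 % of channel variance that cancels in the
bipolar montage. Independent channels are scaled by 1/√2 so the *bipolar*
RMS matches the target. The flat-band model gives analytic control of the
median frequency; it is not a motor-unit action-potential train, so it
reproduces none of the waveform morphology, innervation-zone structure or
firing statistics of real sEMG — parameter-recovery results say the pipeline
is arithmetically correct, not that it is clinically validated. Artifacts
(dead electrodes at 0.1 % of median amplitude, 50 Hz sine of set amplitude,
10× movement bursts of 0.5 s) are injected per an explicit channel list.

**Feature level.** Subjects are drawn from a correlated log-normal model per
etiology group: log-sd from the coefficient of variation (default 0.35, a
typical between-subject spread for surface-EMG magnitudes), correlation 0.7
between the two states of one ring and 0.5 within a modality across rings,
zero across modalities; the log-mean is offset so arithmetic means equal the
specified group means. The default group means are anchored to the published
significant group differences of the clinical cohort (e.g. neurogenic
resting MF ≈ 115–120 Hz vs control ≈ 94–97 Hz; myogenic resting MF
depressed; neurogenic contracted RMS roughly halved). The printed table is
partly garbled in the available source, so the anchor set is a conservative
parse; cells with no published group difference default to the control
value, and control cells never published (RMS3R, RMS2C, the contracted-state
MFs) are plausible interpolations between their printed neighbours. All
anchors are configurable and no acceptance figure depends on them. True
between-feature covariance in the patient population is unpublished:
parameter-recovery claims use the simulator's own ground truth only.

A separate `separable_design` benchmark gives each class a 2–3 log-sd
signature across several features (neurogenic: resting MF up, contracted
RMS down; myogenic: all MF down; idiopathic: resting RMS up, contracted MF
up). It exists to verify that tree induction approaches the Bayes optimum
when the classes genuinely separate — ten-fold CV accuracy on 500 subjects
per class runs 94–96 % across seeds — and deliberately does not model the
clinic, where a CV-0.35 overlap around the published anchors leaves the
idiopathic/control contrast (a single ~14 % MF3R shift) far below noise.

FISI severity scores are simulated as truncated normals (study
N(42, 11²) → [11, 61]; control N(4, 1²) → [0, 5]) purely to exercise the
eligibility rules: study candidates need FISI > 10 (strict), controls ≤ 5.

## Problem sizes and determinism

Default test and acceptance runs use one 12-epoch 10-s session for signal
round-trips, 500 subjects per class for the benchmark CV, and 10⁴ per class
for law-of-large-numbers checks — sizes at which every stochastic tolerance
(RMS within 5 %, MF within 2 Hz, CV accuracy above 90 %) holds with a wide
margin. Every random draw flows from an explicit seed through
`numpy.random.SeedSequence`, so traces, cohorts, fold assignments and
selected trees are bit-reproducible; rerunning any CLI command from its
stored run config reproduces its outputs byte-for-byte.

## Known limitations

* The flat-band signal model cannot probe MF estimators' behaviour on real,
  non-stationary sEMG spectra.
* QC thresholds are surrogates for an unpublished exclusion rule.
* Published split thresholds of the three reference trees are not
  machine-readable; topology and performance arithmetic are reproduced, not
  the trees themselves.
* Specificity values reported here follow the documented one-vs-rest
  definition and will not match reference values whose definition is
  unknown.
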