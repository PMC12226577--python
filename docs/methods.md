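# Methods

This note records the models, parameter choices and known limitations of
the `doorecg` pipeline, in the order data flows through it.

## Synthetic cohort model

Each synthetic subject is a fixed beat template plus a session noise
model; recordings are template pastings at stochastic R times with
additive disturbances.

**Beat template.** A sum of Gaussians forms the P-QRS-T base. The QRS
components are deliberately smooth (SDs ≥ 8 ms, so essentially no energy
above 40 Hz); the subject-specific 40–150 Hz content is carried entirely
by 6–10 Gabor atoms (Gaussian-windowed cosines, carriers drawn in
45–145 Hz, envelopes 6–14 ms, centers within −30…+50 ms of R). This
mirrors the physiology of high-frequency QRS analysis, where the
biometric information lives in notches and slurs superimposed on an
otherwise smooth complex, and it makes the Filter-2 (40–150 Hz) output
almost purely subject-specific: removing the atoms removes >80 % of the
Filter-2 RMS. Atom amplitudes are normalized so the atoms carry 8–15 %
of the QRS-window energy. The T peak sits 200–245 ms after R, consistent
with the shortened QT at the heart rates used. All draws are functions
of one integer seed.

**Heart rate.** Per-subject resting rate is drawn uniformly in
72–88 bpm — standing, hand on a doorknob, not supine — with
beat-to-beat RR drawn from a Gaussian (default SD 2 bpm) truncated at
±3 SD. The ≥72 bpm floor also guarantees a five 20-s-record session
yields >100 usable beats per subject. The first beat starts 0.6 s into
each record, clear of the detector's 0.5 s edge exclusion.

**Noise model.** Additive white noise, 50 Hz mains hum, sinusoidal
baseline wander (<0.5 Hz), Poisson motion-artifact bursts
(Gaussian-windowed noise transients, ~0.25 mV, 40–120 ms), and a
multiplicative session gain `amplitude_scale`. Two presets:

| preset | white SD (mV) | hum (mV) | wander (mV) | bursts/min |
|--------|---------------|----------|-------------|------------|
| dispo  | 0.09          | 0.008    | 0.05        | 0          |
| door   | 0.28          | 0.075    | 0.15        | 1          |

The door preset is roughly 3× the dispo broadband level plus hum and
bursts. Its magnitude was calibrated once so that single-beat (no
averaging) 10-subject identification lands in the high-80s percent —
the regime a doorknob-grade electrode is expected to produce — leaving
the headroom that synchronized averaging then recovers. Different-day
sessions redraw `amplitude_scale` per subject from a lognormal with 10 %
log-SD (sock thickness, perspiration, electrode coupling), and change
nothing else; the subject template never varies across sessions. An
optional 50 Hz notch emulating the acquisition front end is available
but off by default, since residual hum is useful for testing.

**What the simulator does not emulate:** respiration coupling,
heart-rate drift, arrhythmia, electrode-circuit dynamics, within-subject
morphology change. Synthetic results therefore demonstrate that the
pipeline's mechanisms work (averaging gains, augmentation gains, drift
contrasts) — not that its absolute accuracies transfer to real
recordings.

## Filtering

Both cascades are Butterworth IIR designs applied zero-phase
(forward–backward, `sosfiltfilt`): Filter 1 = HP 0.5 Hz order 4 → LP
150 Hz order 12; Filter 2 = HP 40 Hz order 4 → LP 150 Hz order 12.
Orders are the designed single-pass orders; the −3 dB point is checked
on the single-pass response. Zero-phase application was chosen because
R-peak times found on the Filter-1 path index directly into the
Filter-2 series — causal filtering would require group-delay
compensation between two cascades of different phase response. Padding
for the zero-phase pass is stretched to ~3 time constants of each
stage's cutoff (the 0.5 Hz stage needs seconds, far beyond the library
default, or its edge transient leaks across short records). Inputs
shorter than 3× twice the stage order are rejected.

## R-peak detection

Candidates are positive local maxima of the Filter-1 output at least
250 ms apart that exceed 0.5× the rolling 2-s maximum of |x|; the first
and last 0.5 s are excluded (filter transients). Each candidate is then
refined to the maximum within ±25 ms of a 30 Hz low-passed copy of the
signal — refining on the raw band signal jitters the anchor by ±10–15
samples under door-grade noise, which de-phases downstream averaging,
whereas the smooth-copy anchor is consistent to ~1 sample (it may carry
a small constant per-subject offset, which is harmless and itself
subject-specific). Finally, peaks below 0.6× the median kept-peak
amplitude are pruned: R amplitudes within one recording are stable, and
this rejects stray T-wave detections that survive the refractory rule.
Under the door preset the detector scores ≥0.99 sensitivity and
precision against simulator ground truth.

## Segmentation and synchronized averaging

Segments are exactly 200 samples, `[R−75, R+125)`, 0-based half-open;
peaks too close to a record edge are skipped and counted. Averaging
combines n ∈ {1,…,5} *consecutive* segments of one recording —
sliding (stride 1, the default; overlapping groups maximize the number
of averaged segments from a 20-s record) or block (disjoint groups, for
strictly independent segments). Averaged segments inherit subject and
recording identity and record the source-beat ordinals; averaging never
crosses recording boundaries, and non-finite segments are dropped first.
The implemented noise law is the standard one: per-sample noise variance
σ²/n, amplitude SNR gain √n, verified by Monte-Carlo tests.

## Datasets and the leakage guard

The 70/30 train/test split happens at the *source-beat* level before any
averaging: within each recording a contiguous 30 % window at a seeded
random position becomes test, the remainder train, and averages are then
formed within each side. Splitting already-averaged segments would let
sliding averages share source beats across the boundary and bias
accuracy upward. The cost is that each side loses n−1 beats per
contiguous fragment; with five 20-s records per subject the stated
compositions (70 training segments per source type, 30 three-averaged
test segments) become infeasible at n = 5. Experiment corpora in this
package therefore use **twelve** 20-s records per subject (4 min of
signal) — the acquisition-protocol record length is kept, the count
raised as the package's own corpus choice; the simulator default remains
five records.

Training compositions (counts per subject): `1avg-70TD`, `2avg-70TD`,
`3avg-70TD` (70 segments of one type); `1,2avg-140TD`, `1,3avg-140TD`,
`2,3avg-140TD` (70 + 70); `1,2,3avg-210TD` (70 + 70 + 70). "Mixing
randomly selected segments" is interpreted as random *selection of*
consecutively-averaged segments, not averaging of non-consecutive beats.
Test sets draw a fixed count (default 30) per subject at a single
averaging depth (default 3). All draws are seeded and balanced across
subjects; shortfalls raise errors naming the subject and missing count.

## Classifiers

**Neural network.** 200 → 100 (ReLU) → K (sigmoid), trained with mean
per-unit binary cross-entropy against one-hot targets — the natural
pairing for a sigmoid output layer — decoded by argmax (ties to the
lowest label index). Adam (lr 0.001, β₁ 0.9, β₂ 0.999), batch 16, 200
epochs by default, per-epoch seeded shuffling, uniform ±1/√fan-in
initialization, no early stopping, no input normalization by default
(per-segment standardization available behind a flag). The net is
implemented directly in numpy, which keeps training bit-deterministic
for a given seed. Sweep runners accept a reduced epoch count; the
shipped experiment scripts use 40 epochs, which reaches the same
accuracy plateau on the synthetic corpus at a quarter of the cost.

**SVM.** Linear soft margin, C = 1, one-vs-rest, fitted with
scikit-learn's `LinearSVC` (primal, deterministic). The one-vs-rest
scheme is the conventional default for a linear multiclass SVM.

## Evaluation

Accuracy is trace/total of the K-class confusion matrix — the K-class
generalization of (TP+TN)/(TP+TN+FP+FN); one-vs-rest TP/FN/FP/TN
reductions and per-class recall (per-subject accuracy) are also exposed.
Every condition runs 10 cycles; cycle c re-draws the split membership,
dataset sampling and NN initialization from `base_seed + c`. The SD
column is the sample SD (ddof = 1) over cycle accuracies. The
different-day evaluation applies an already-trained model to another
session's data without retraining, restricted to registered subjects
(closed set).

## Numerical and degenerate-input policy

Flat or empty series yield an empty peak list, not an error; an
all-skipped extraction yields an empty segment list plus a warning
count. Averaging with n larger than the available segments returns
empty with a warning; mixed-subject or mixed-recording averaging is an
error. Confusion matrices reject labels outside the declared order;
accuracy on an empty matrix is an error. Filter designs reject cutoffs
at or above Nyquist. Seeds below 2³¹ everywhere.

## Known limitations

- Simulator realism as listed above; in particular amplitude drift is a
  pure gain, so the NN-vs-SVM drift contrast is tested directionally,
  not calibrated to any real-world effect size.
- The beat-level split guard changes the segment-sampling distribution
  relative to a naive post-averaging split (test windows are contiguous
  runs), which is the price of excluding source-beat leakage.
- Open-set operation (impostor rejection, FAR/FRR) is out of scope; the
  classifier always answers with a registered identity.
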