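# Methods

## Scope and data model

The package operates on `ImuSession` objects: one labeled subject with five
sensor nodes (head, left/right wrist, left/right ankle), each carrying six
equal-length channels (3-axis acceleration in g, 3-axis angular velocity in
deg/s) on a uniform grid at `fs` (default 30 Hz). Missing samples are NaN
sentinels and are never dropped; every downstream stage requires finite
input, so cleaning is explicit. Clinical labels are `Normal`, `LowRisk`,
`HighRisk`; the binary view pools the two risk grades as `Risky`.

## Synthetic cohorts

No public recordings exist for this problem, so the generator is
first-class, tested code rather than a fixture. Its movement model is
deliberately simple: per channel, Gaussian noise low-passed at 10 Hz
(order 2, single pass, so the roll-off stays soft through the 0–14 Hz
analysis band) is modulated by a non-negative burst envelope (squared
clipped 0.4 Hz noise with a small tonic floor) and scaled by a per-node
amplitude (0.08–0.35 g, 10–55 deg/s; limbs move more than the head).
Acceleration channels ride on a constant per-node gravity orientation.

Class contrasts:

* **Amplitude** — Risky channels are the same process divided by
  `effect_scale` (default 2.0, the middle of the roughly 1.5–2.5× range the
  projected scatter contrast suggests). Because power scales with the
  square of amplitude, Normal sessions also have uniformly higher 0–14 Hz
  spectral power, which the group-band tests verify bin-wise.
* **Bulges** — Risky sessions receive Poisson(`bulge_rate` × minutes)
  isolated 1–2 s Gaussian pulses of high amplitude on a random node
  (default 0.5/min).
* **Noise** — both classes get sensor noise high-passed above 14 Hz
  (order 6, zero-phase, so it stays out of the analysis band).
* **Missing data** — i.i.d. NaN sentinels at `missing_rate` (default 0.2%),
  never on the first or last sample, so linear interpolation is total.

Generation is a pure function of (label, spec, seed); per-subject seeds are
derived from `(cohort_seed, subject_index)` so growing a cohort never
perturbs existing subjects.

What the generator does **not** emulate: biomechanical limb coupling,
posture changes, nonstationary circadian structure, device dropout bursts,
or the uneven recording lengths of real cohorts. Passing tests therefore
demonstrate that the pipeline recovers the statistical structure it assumes,
not that it would reach any particular accuracy on clinical data; the
published clinical accuracies are not reproducible without the recordings
and are not claimed.

Vital traces are bump/transient trains with multiplicative interval jitter
(2% SD): Gaussian bumps of width 0.3×period for respiration (sinusoid-like)
and 0.1 s for pulse/heartbeat. True event times are returned so rate
estimators can be scored against ground truth.

## Preprocessing

* **Cleaning** — NaN runs are linearly interpolated between nearest present
  neighbors; leading/trailing sentinels (possible in external data) take
  the nearest value; an all-NaN channel is an error.
* **Filtering** — Butterworth, order 4, zero-phase (forward-backward) by
  default; zero-phase preserves peak timing for the rate estimators at the
  cost of squaring the magnitude response. Padding is 10 cycles of the
  lowest corner frequency, which keeps edge transients out of the analyzed
  span for the narrow low-frequency bands. Cutoffs: 14 Hz low-pass before
  segmentation; 0.08–0.9 Hz (respiration), 1–5 Hz (pulse). The heart chain
  has no published band; 0.7–8 Hz was chosen to cover 42–220 bpm
  fundamentals at fs = 30 Hz.
* **Segmentation** — fixed 120 s windows, 10 s overlap, partial tail frames
  dropped (downstream matrices need equal-length frames). The closed-form
  count ⌊(L−W)/(W−V)⌋+1 is property-tested against brute-force enumeration.
* **Peak detection** — `scipy.signal.find_peaks` with prominence ≥
  `min_prominence_sd` × SD and a minimum separation; when two candidates
  collide the larger wins (scipy's rule), ties resolve to the earlier.
* **Rates** — respiration/pulse use peak count × 60 / duration; heart rate
  uses the median inter-peak interval (robust to one missed R peak) after
  parabolic sub-sample peak refinement — at 30 Hz the raw sample grid
  quantizes intervals by several bpm at infant heart rates. A trace whose
  passband holds < 10⁻⁴ of total power is reported as NaN (undefined)
  rather than yielding spurious peaks. Validated ranges at zero noise:
  respiration 15–50/min (±1), pulse 70–180/min and heart 50–150/min
  (±2 bpm); below ~66/min the 1–5 Hz pulse band attenuates the fundamental
  and the chain locks onto the second harmonic, an intrinsic property of
  that band, not of the implementation.
* **Spectra** — one-sided periodogram of the demeaned channel; Hann window
  by default for group comparisons, boxcar available (and used by the
  conservation test, where sum × Δf equals the variance exactly). Group
  bands are mean ± sample SD of dB power across subjects; the overlap rate
  between two groups is the mean over frequency bins of
  |intersection| / |union| of the two mean ± 1 SD intervals (0 when
  disjoint), × 100. The alternative reading of "coverage magnitude" (raw
  min/max magnitude ratios) is isolated behind this one function if it ever
  needs swapping.

## Feature catalogs

The 29 time/frequency features (per fused channel, fixed order, catalog
version 1.0): mean, SD, variance, RMS, min, max, peak-to-peak (`p2`),
median, IQR, skewness, kurtosis, mean absolute deviation, zero-crossing
rate of the demeaned signal, signal magnitude area, mean energy, crest /
impulse / shape factors, waveform length, lag-1 autocorrelation, dominant
frequency and its power, spectral centroid and spread, spectral entropy,
band powers 0–2 / 2–6 / 6–14 Hz, median frequency. Zero-variance inputs
take explicit conventions (moment shapes, ratio features and spectral
features are 0) so matrices are always finite. Scale behavior
(amplitude-proportional vs scale-free) is asserted per feature in tests.

The 7 entropy features: approximate entropy (m=2, r=0.2·SD), sample entropy
(m=2, r=0.2·SD, both template lengths over N−m starting points; the maximal
finite value is returned when no (m+1)-matches exist), permutation entropy
(order 3, delay 1, natural log, stable tie-break), spectral entropy
(normalized), Shannon entropy of a 16-bin amplitude histogram, fuzzy
entropy (m=2, Gaussian membership on demeaned templates), and SVD entropy
(embedding 10). The quadratic-time template entropies are numba-compiled
and verified against naive-loop oracles; they are evaluated on the first
1024 samples (≈34 s) of each frame, since O(n²) matching over the full
3600-sample frame adds cost without improving the estimate materially
(template-entropy literature typically uses N ≈ 100–5000).

One caveat discovered during validation: white noise exceeds an
equal-variance pure tone on every *temporal-complexity* entropy, but not on
the amplitude-histogram Shannon entropy — a sinusoid's arcsine value
distribution spreads across bins more evenly than a Gaussian. The ordering
property is asserted for the six complexity measures only.

Both catalogs are fixed and versioned; column order is part of the package
contract (descriptors `node.channel.feature` round-trip through CSV).
Spectral entropy intentionally appears in both catalogs.

## Selection, balancing, evaluation

* **Ranking** — per feature, two-sided two-sample Student *t*-test with
  pooled variance (the classic `ttest2` default; Welch is a switch).
  Undefined statistics (zero variance, equal means) take p = 1 and rank
  last; ties break by column index. Type-I calibration under the null is
  asserted at the 95% binomial interval.
* **Selection** — top 10 features with p < 0.05 per matrix; shortfalls are
  recorded, not padded.
* **Equal-weight processing** — per-column z-scoring of the concatenated
  60-feature table, with center/scale retained for held-out rows. (The
  alternative reading — uniform weights in a distance metric — was
  rejected because only standardization makes heterogeneous feature scales
  commensurable for every model in the zoo.)
* **SMOTE** — synthetic minority rows interpolate between a minority point
  and one of its k=5 nearest minority neighbors; all original rows are
  preserved verbatim; classes end exactly balanced. A minority of size
  ≤ k reduces k with a warning (strict mode raises); a singleton minority
  falls back to duplication with a warning.
* **Protocol** — stratified 80/20 hold-out, 50 rounds; 5-fold CV accuracy
  inside the training split recorded per round for model assessment;
  metrics computed on the untouched test split; means ± SD over rounds ×
  repeats. Two SMOTE placements are provided: `train_only` (default;
  selection, standardization and SMOTE re-fitted per round inside the
  training split, so no information flows from the test split) and
  `pre_split` (whole-dataset balancing before splitting, mirroring the
  common but leak-prone protocol). Two split granularities: `frame`
  (overlapping frames of one subject may cross splits — measurably inflates
  accuracy) and `subject` (frames move with subjects). In the three-class
  protocol, feature ranking remains defined on the binary Normal/Risky
  contrast; only the classifier sees three labels, and multiclass metrics
  are macro-averaged one-vs-rest.
* **Model zoo** — the three named models are LR, SVM, MNB (MNB behind a
  [0,1] rescaler because it requires non-negative input); the remaining six
  are fixed as common IMU/HAR baselines: KNN, DT, RF, GNB, AdaBoost, GBDT.
  All stochastic fits are seeded. A CNN variant is out of scope: no deep
  learning framework is a dependency of this package.
* **Dimension sweep** — hybrid dimension d allocates ⌊d/6⌋ features per
  matrix; the remainder goes round-robin to the matrices whose next
  candidate feature has the smallest p-value.

## Parameter-recovery experiment

The pipeline's end-to-end sanity check asks whether classification accuracy
tracks the generator's class contrast. It uses a class-balanced cohort
(9 Normal / 4 LowRisk / 5 HighRisk ⇒ 9/9 binary, 360 s sessions, 54 frames)
with subject-level splits, so chance level is well defined at 0.5. The
no-signal condition sets `effect_scale=1.0` **and** `bulge_rate=0` (both
class contrasts nulled) and averages over three independent cohort seeds,
because accidental between-group separation within one 18-subject cohort
dominates the variance (single-cohort no-signal accuracies ranged
0.43–0.60 during development; the acceptance band 0.5 ± 0.1 is two standard
errors of the 3-cohort mean). At `effect_scale=3.0` accuracy must reach
≥ 0.95, and accuracy must be non-decreasing (within 0.05) across
effect scales {1.0, 1.5, 2.0, 3.0}.

## Problem sizes and determinism

Default study-scale runs use 18 subjects × 360 s at 30 Hz (54 frames), 50
hold-out rounds, 1000-case oracle sweeps and 100-seed rate-recovery trials.
All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; reports embed their full protocol, and the
pipeline manifest (config + seeds + version) reproduces every number
bit-for-bit.

## Known limitations

* The 29/7 feature identities are a fixed, documented catalog; if the
  original study's exact tables surface, the catalog module isolates the
  change.
* Frame-level splitting is provided for protocol fidelity but leaks subject
  identity through overlapping windows; subject-level results are the
  defensible ones and both are reported.
* The synthetic movement model makes no physiological claims; absolute
  accuracies on it do not transfer to clinical recordings.
* `pre_split` SMOTE assigns no subject identity to synthetic rows, so it is
  incompatible with subject-level splitting by construction.
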