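# Methods

`iatropy` implements an analysis pipeline linking EEG signal complexity
during Implicit Association Test (IAT) processing to subsequent exercise
behavior, together with a synthetic-data generator that makes every stage
testable without access to patient recordings.

## Behavioral scoring

**IAT D-score.** For one IAT (affective or instrumental), practice trials
are removed; formal trials with a missing response or RT < 350 ms are
discarded; a participant whose error rate (incorrect / formal trials)
exceeds 20% in either block is excluded from that IAT. Incorrect retained
trials receive an effective RT equal to the mean correct RT of their block
plus 400 ms. Then

    D = (mean RT_incompatible − mean RT_compatible) / SD_pooled,

where the means use effective RTs of all retained trials and `SD_pooled`
is the sample SD (n−1 denominator) of the *union* of correct-trial raw RTs
from both blocks. The phrase "pooled standard deviation" is ambiguous
between this union SD (the convention of the improved IAT D algorithm) and
the classical two-sample pooled estimator; the union SD is the default and
`sd_mode="two_sample"` selects the alternative. The processing order
(practice removal → RT filter → error-rate check → penalty → D) is a
documented convention; the error rate is computed over all formal trials of
a block so the 20% rule does not depend on the RT filter.

**Exercise scoring.** MET-min/week per activity class is MET × min/day ×
days/week with walking = 3.3, moderate = 4.0, vigorous = 8.0 METs.
Moderate-to-vigorous activity (MVPA) excludes walking; `non_exercise`
is assigned iff MVPA = 0 MET-min/week — a strict dichotomy.

## Preprocessing

Continuous EEG is downsampled (polyphase, anti-aliased) to 500 Hz,
band-passed 3–40 Hz with an odd-length Hamming windowed-sinc FIR applied
once with group-delay compensation (linear phase ⇒ zero-phase output,
−6 dB at the band edges; the default 3 Hz transition width puts > 40 dB of
attenuation at 1.5 Hz, and the Hamming stop-band (~53 dB) covers 53 Hz).
Epochs span −500..1000 ms around stimulus onset (correct formal trials
only), are baseline-corrected on −200..0 ms, and are rejected whole if any
channel sample strictly exceeds ±100 µV ("exceeding" read as strict
inequality, so a 100.0 µV peak survives). ICA artifact removal and
spherical-spline bad-channel interpolation are deliberately out of scope:
both hinge on visual inspection of real artifacts, synthetic data are
generated clean, and real-data mode expects pre-cleaned input. Mastoid
re-referencing is a pass-through hook for the same reason.

The analysis montage is the 14 region electrodes: frontal (Fz, F1, F2),
fronto-central (FCz, FC1, FC2), central (Cz, C1, C2), centro-parietal
(CP1, CP2), parietal (Pz, P3, P4).

## Entropy panel

All metrics are computed per epoch × electrode, averaged over epochs, then
over the electrodes of a region (means commute; this order is the
implemented one). The default segment is the full −500..1000 ms epoch; a
post-stimulus mode is available, in which the singular-spectrum window is
auto-shrunk (see below). Conventions, with tunables in `EntropyConfig`:

- **Approximate entropy** (m = 2, r = 0.15 × SD, Chebyshev distance,
  self-matches included): Φ^m − Φ^{m+1} with Φ^m the mean log fraction of
  templates within r. SD is the population SD of the analyzed segment;
  an absolute-r mode exists.
- **Sample entropy**: −ln(A/B) over template *pairs*, both lengths drawn
  from the first N−m templates; A = B matches at length m+1 / m. Undefined
  (no matching pairs) returns NaN, which regional averaging excludes and
  counts in `n_undefined`, never imputes.
- **Fuzzy entropy** (Chen-style): templates are mean-centered, membership
  exp(−(d/r)^2), N−m templates at both lengths; ln φ^m − ln φ^{m+1}.
- **Permutation entropy** (order 6, delay 1): Shannon entropy of ordinal
  patterns of consecutive 6-tuples; ties broken by index order (stable
  argsort — measure-zero for continuous data); a normalized variant
  (÷ ln 720) is exposed.
- **Envelope entropy**: Shannon entropy of the Hilbert amplitude envelope
  normalized to a probability vector (maximum ln N for a constant
  envelope). Note the envelope of an impulse retains 1/|t| tails, so
  "concentrated" signals reach roughly 0.5–0.6 ln N, not 0.
- **Singular spectrum entropy**: Shannon entropy of normalized singular
  values of the lagged (Hankel) trajectory matrix, window L = 500 samples
  on full epochs. Probabilities use σ (not σ²) normalization by default;
  both variants are exposed because published definitions differ. When a
  segment is shorter than L (e.g. post-stimulus mode), L shrinks to 2N/3
  with a warning — at L = 500 a 500-sample segment would give a degenerate
  one-column trajectory.
- **Log energy entropy**: Σ log(x² + ε) with ε the smallest positive
  normal double; the only metric that is not scale-free (it shifts by
  exactly N·log k² under x → kx, asserted in tests).

The O(N²) template estimators are numba kernels (ApEn/SampEn share one
pair sweep; fuzzy distances are computed branch-free and exponentiated in
one vectorized pass); singular values come from the Gram matrix of the
smaller trajectory side, whose √ε-level error on near-zero singular values
is invisible to the entropy (p ln p → 0). Every estimator is checked
against an independent brute-force implementation to 1e-10 on random
signals.

## Group statistics

Each region × metric feature is compared between groups with a two-sided
Wilcoxon rank-sum test (normal approximation, tie-corrected variance,
0.5 continuity correction; exact enumeration backs the tests). z is
reported negative when the exercise group has the higher mean rank, so
"exercisers higher" prints negative z; the raw convention is a switch.
Within each task condition the 5 × 7 = 35 tests form one
Benjamini–Hochberg family at q = 0.05; conditions are not pooled because
they index distinct processing contexts. `EntropyGroupComparison.fit()`
returns a results object with the stat table and a text summary.

## Classification

`ExerciseClassifier` evaluates RF / KNN / SVM / LDA on a chosen feature
block (D-scores, the full 7 × 5 entropy panel, or envelope-only, crossed
with IAT type and block scope). The protocol is 10 repetitions of
stratified random 70/30 train/test splits; the description "70/30 split
evaluated with ten-fold cross-validation" is internally inconsistent, and
repeated splits match both the 70/30 sentence and mean ± SD reporting; a
plain stratified k-fold mode is the config alternative. Fixed
hyperparameters: RF 100 trees, min leaf 5; KNN 5 Euclidean neighbors; SVM
RBF with C = 1 and the median-heuristic kernel scale estimated on the
training split (deterministic, no inner CV); LDA with least-squares solver
and automatic shrinkage when features ≥ training samples. Features are
standardized with training-split statistics for KNN/SVM/LDA (RF is
scale-free); whether the original protocol standardized is unstated, so it
is a flag. The positive class is `non_exercise` everywhere. Metrics
(accuracy, sensitivity, specificity, precision, F1, in percent) come from
per-repeat test confusion matrices; ROC/AUC pools test scores over repeats
and equals the Mann–Whitney rank statistic (pair-counting oracle in
tests). RF impurity importances are averaged over repeats; the top five are
renormalized to their own total, labeled e.g. `FC_A_IC` (fronto-central,
affective incompatible).

## Synthetic cohorts

The generator emulates the statistical structure the analysis consumes,
not biophysics. Per epoch and channel:

    x(t) = env(t) · Σ_b A_b cos(2π f_b t + φ_b) + noise(t) + erp(t)

with carriers at 5/10/22 Hz (6/10/5 µV), 1/f background noise (3 µV RMS,
3–45 Hz), a small stimulus-locked Gaussian potential (4 µV at 300 ms), and
env(t) = clip(1 + β·s(t)) where s(t) is unit-variance 0.3–3 Hz noise.
The modulation depth β ("burstiness") is the one dial the headline metric
reads: β = 0 gives a near-constant envelope (envelope entropy at its
maximum), larger β lowers it monotonically (tested on a grid).

Participants draw a latent burstiness trait (SD 0.10 around a base of
0.45); the planted effect subtracts `effect_size_d × trait SD` from β for
exercise-group participants, only in the effect conditions × regions
(default: affective-incompatible × frontal/fronto-central/central), so
exercisers have *higher* envelope entropy there. Because the regional
envelope feature is a nearly linear, low-noise readout of β (channel and
epoch averaging suppress estimation noise), the realized standardized
feature difference tracks `effect_size_d`; Monte-Carlo calibration in the
tests confirms agreement within ±0.3 at d = 1.5. The default
`effect_size_d = 1.0` represents the large, robust group difference the
analysis is designed to detect (the reported fronto-central envelope
z ≈ −3.8 at n = 33/23 corresponds to a standardized difference near 1).
Trial logs use ex-Gaussian RTs (µ = 550 ms, σ = 80, τ = 120) with an
+80 ms incompatible-block shift and configurable error (8%), fast-response
(2%) and missing (1%) rates; exercise recalls satisfy the MVPA group rule
by construction. All randomness flows from one root seed through named
substreams (participant × stage × condition), so cohorts are bit-identical
under a seed and adding participants leaves existing ones unchanged.

What the generator does *not* emulate: volume conduction and realistic
channel covariance, artifacts beyond an optional amplitude-spike injector,
non-stationarity across the session, and any coupling between D-scores and
EEG complexity. Passing tests therefore demonstrate that the pipeline
recovers what it is designed to measure under its own assumptions — not
that those assumptions hold for real EEG.

## Validation problem sizes

Monte-Carlo validation runs a scaled-down version of the study conditions:
200 Hz native / 100 Hz analysis rate, 2–4 formal trials per block
(≈ 2–4 clean epochs per condition), post-stimulus entropy segment with an
SSE window of 30 samples, while keeping the full 56-participant 33/23
design, all four conditions, 14 electrodes and the 7 × 5 feature panel.
These sizes were chosen once as the package's desk-scale defaults; the
calibration experiments above show the planted effect is essentially
insensitive to the epoch count at this averaging depth.

Null calibration (200 cohorts, no effect) bounds the per-family
probability of any FDR rejection by q + 2 × MC error; measured ≈ 0.02–0.04
at q = 0.05. Planted-effect recovery at d = 1.0 yields per-cell
FDR-significance rates of ≈ 0.55–0.65 (100 replicates): with ~3–8
discoveries in a 35-test family, BH implies an effective per-test α of
0.004–0.011, and the rank-sum noncentrality at n = 33/23 and d = 1 (~3.5)
then caps per-cell power near 0.6–0.7. This is a genuine property of the
protocol at this sample size, and the corresponding acceptance test states
the 80% recovery target it fails to reach; the planted effect size was not
inflated to mask it. The classifier contrast is robust: RF on
affective-incompatible envelope features beats a shuffled-label baseline by
≈ 15–20 accuracy points (20 seeds), and the top-5 RF importances recover a
planted frontal/fronto-central/central affective-incompatible envelope
feature in ~100% of seeds.

## Degenerate inputs and tie-breaks

Constant signals return 0 for ApEn/SampEn/FuzzyEn (all distances zero);
all-zero signals raise for envelope and singular-spectrum entropy (no
envelope / spectrum); SampEn with zero matches returns NaN and is excluded
from averages; rank-sum with all-identical values returns z = 0, p = 1;
BH on an empty family returns an empty family; a classification test split
that loses a class is skipped with a log message (unreachable under
stratified splitting); participant-conditions whose epochs are all
rejected raise a dedicated exclusion signal.
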