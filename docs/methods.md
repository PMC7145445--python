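# Methods

## Scope and data model

The package analyses continuous-wave fNIRS recordings from a 46-channel
infant headgear (23 channels per hemisphere, 2 cm source–detector
separation, wavelengths 770 and 850 nm, 10 Hz sampling). The study design
is fixed by configuration: four conditions in two modalities (spoken:
English, French; signed: BSL, LSFB), stimuli 9–12 s long alternating
between modalities, 10-s baselines, at most 20 experimental trials per
infant, and three participant groups (monolingual, unimodal bilingual,
bimodal bilingual). Channel ids are integers 1–46 with 1–23 on the left;
hemisphere is a categorical property of the channel, not derived from
geometry. Time is seconds from recording start; epochs use half-open
sample windows at 10 Hz, so a 24-s block holds exactly 240 samples.

The montage's channel→anatomy lookup is not public beyond ROI membership,
so anatomical labels in the shipped configuration are placeholders; the
two ROIs (inferior frontal, posterior temporal; 8 channels each, 4 per
hemisphere) are configuration, validated against the montage at load time.

## Channel quality control

Screening runs per wavelength on the full-session signal; a channel fails
if **any** wavelength fails **any** criterion (the conservative OR rule,
chosen because noise characteristics can differ between wavelengths):

- **Coefficient of variation** `100·sd/mean > 15%`. Computed on intensity
  by default; `cov_domain: attenuation` switches to log-attenuation.
- **Normalized peak power**: the largest periodogram bin at or above
  0.5 Hz, as a fraction of total non-DC power, `> 50%`. The criterion is
  meant to catch strong periodic components *unrelated to the experiment*
  (instrumental oscillations, poorly coupled optodes); the stimulus-locked
  hemodynamic response occupies the band below ~0.3 Hz, so the peak-bin
  search floor (`npp_min_frequency_hz`, default 0.5 Hz) keeps a perfectly
  clean recording from being flagged for its own evoked response. The
  denominator remains the total non-DC power so that a genuinely dominant
  oscillation is still scored against everything else in the signal.
- A session-level linear-drift criterion exists but is disabled by default
  (no principled threshold is available).

Infants with more than 15 rejected channels are excluded from all
analyses (strict inequality: exactly 15 is retained). All thresholds are
configuration; the defaults are the protocol values.

## Preprocessing

Order of operations: low-pass filter the intensity, convert to attenuation
change −ln(I/Ī) against the session mean, segment into onset-locked
[−4, 20) s blocks, detrend, convert to concentrations, then reject trials.

- **Filter**: Butterworth low-pass, order 4, cutoff 1.7 Hz, applied
  forward–backward (`sosfiltfilt`), so phase is exactly zero, DC gain is 1,
  and the effective order doubles; attenuation at an infant cardiac 2.4 Hz
  is ≈25 dB. Order and cutoff are configuration.
- **Detrend**: subtract the straight line through the means of the first
  and last 4 s of each block (anchored at the window centers). Both
  end-window means are exactly zero afterwards. This removes slow drifts
  and trial-to-trial activation build-up.
- **Beer–Lambert inversion**: per time point, solve the 2×2 system
  ΔA = E·ΔC·10⁻³·d·DPF for ΔC = (HbO₂, HHb) in μmol, with extinction
  coefficients (mM⁻¹cm⁻¹) from the Cope compilation at 770/850 nm shipped
  as *data* in the configuration (swappable), d = 2 cm, DPF = 5.13.
  Detrending and the inversion are linear operators on different axes and
  therefore commute exactly.
- **Re-referencing**: concentrations are referenced to the pre-stimulus
  4-s mean, which defines the "change" that the rejection thresholds and
  peak amplitudes measure.
- **Trial rejection** (per channel, per chromophore, strict inequalities):
  |ΔC| > 3 μmol anywhere in [−4, 0) s, or > 5 μmol anywhere in [0, 10) s.
  The stimulus window is fixed at the nominal 10 s even though real stimuli
  span 9–12 s, matching the 4+10+10 epoch arithmetic.
- **Looking-time criterion**: trials watched for < 60% of their duration
  are dropped (missing proportions drop the trial with a warning).
- **Averaging and inclusion**: channel means use only trials valid in that
  channel; QC-rejected channels are NaN throughout. A trial counts as
  *overall valid* when it is valid in at least 50% of retained channels
  (`trial_validity_rule`, configurable — the protocol defines validity per
  channel only, so a cross-channel rule had to be chosen). A condition is
  included with ≥ 3 overall-valid trials *and* an included modality
  partner (excluding English also excludes French, and vice versa);
  modality averages (spoken = English+French, signed = BSL+LSFB) require
  ≥ 3 overall-valid trials pooled over the modality.

## Univariate statistics

Peak amplitude is the signed window extremum in [8, 16] s post-onset —
maximum for HbO₂, minimum for HHb — rather than the maximum absolute
value, because the downstream activation logic and the ROI lateralization
contrasts are directional (right-hemisphere *deactivation* must come out
negative). Channel maps use one-sample two-tailed t tests against zero
(the pre-stimulus baseline is the zero reference after re-referencing),
with Benjamini–Hochberg FDR computed over m = 46 channels even when some
channels are missing from a map, so partial maps are corrected against the
full montage. Both uncorrected and corrected maps are reported. A channel
whose HbO₂ and HHb both move significantly in the same direction is
labelled `inconsistent` and never reported as active. Familiarity
contrasts are paired t tests on participant-matched peaks; sign-language
familiarity is only defined for bimodal bilinguals (both sign languages
are unfamiliar to the other groups), enforced by the familiarity map.

## ROI ANOVA

Peak HbO₂ is averaged over each ROI's channels per participant, hemisphere
and modality (cells average whatever channels survived QC; participants
missing a cell are dropped listwise). The 2×2×3 mixed ANOVA exploits the
fact that both within factors have two levels: the subject mean and the
three within-contrast scores (modality, hemisphere, their product) carry
the entire decomposition, so each effect reduces to a one-way
between-group regression on one score. Type-III tests with sum-to-zero
group coding handle the unequal group sizes the way standard mixed-ANOVA
software does: the within main effects test the unweighted mean of group
means. Closed forms are used (intercept SS = M*²k²/Σ(1/n_g); group SS =
classical between-group SS; error = pooled within-group SS). Contrast
scores below 10⁻¹⁰ of the data scale are snapped to zero so degenerate
effects report F = 0 instead of a 0/0 artifact. Effect size is partial η²
= SS_effect/(SS_effect+SS_error). Sphericity corrections are vacuous for
two-level factors. The implementation agrees exactly with
`pingouin.mixed_anova` on balanced one-within designs and with
`statsmodels.AnovaRM` on pure within designs (both cross-checked in the
test suite).

## MVPA decoding

Patterns are per-participant modality-average HbO₂ peak vectors over a
channel subset (all 46, left 23, right 23). Standardization is z-scoring
within channel across **all** contributing patterns, pooled over both
contrast conditions — including the held-out participant, replicating the
published procedure; a leakage-free variant that refits the scaler on each
training fold is available (`leakage_free=True`) for sensitivity analyses.
Channels missing for a participant are imputed at the standardized channel
mean (0). The classifier is a linear soft-margin SVM with C = 1
(`sklearn.svm.SVC(kernel="linear")`); evaluation is
leave-one-participant-out, so each participant contributes exactly two
test trials and accuracy is k/(2n). A zero decision value predicts the
first class in canonical order (deterministic tie rule, flagged together
with degenerate all-identical training folds).

Permutation inference preserves the participant structure: each
permutation keeps or swaps every participant's two labels with an i.i.d.
fair coin (duplicates allowed; an exhaustive mode enumerates all 2ⁿ swap
patterns for small n), reruns the entire leave-one-participant-out
evaluation, and the p value is (1 + #{null ≥ observed})/(n_perm + 1) —
floor 1/1001 at 1,000 permutations. Note that in a strongly decodable
cohort the identity and all-swap patterns also reach the observed
accuracy, so the floor is attained only when neither is drawn. Group and
hemisphere comparisons subtract the two null distributions paired by
permutation index; their p value is the plain fraction of null differences
≥ the observed difference (a zero is below the test's resolution and is
flagged, to be reported as p < 1/n).

## Synthetic cohort generator

The generator is the forward model of the analysis chain, with known
ground truth at every stage. What it emulates, and what it does not:

- **Response**: a gamma-variate `h(t) = A·(t/t_p)^a·exp(a(1−t/t_p))` with
  peak time t_p = 12 s (the observed infant latency for stimuli of this
  kind) and shape a = 50. The shape was chosen once so the response
  resolves within the 10-s post-stimulus baseline (h < 2.5% of A beyond
  ~17 s); this keeps consecutive trials separable and the two-point
  detrend nearly unbiased (residual peak bias ≈ −2%, visible in the
  noise-free recovery test). The cost is a response narrower (FWHM ≈ 4 s)
  than a real block response to a 10-s stimulus. HHb amplitude defaults to
  −⅓ of HbO₂ (canonical asymmetry; unconstrained by protocol, exposed as a
  parameter).
- **Design**: 20 trials, 5 per condition, strict modality alternation,
  stimulus durations drawn uniformly from 9–12 s (which also prevents the
  evoked response from concentrating into single FFT bins, as an exactly
  periodic design would), 10-s baselines, onsets snapped to the sampling
  grid. Looking proportions are Beta(9, 1) (mean 0.9, ~1% of trials below
  the 60% criterion).
- **Noise** (attenuation units; 1 μmol HbO₂ ≈ 0.0067 AU at 770 nm):
  cardiac oscillation at 2.4 Hz — an infant heart rate, deliberately above
  the 1.7 Hz cutoff so filtering is testable — with amplitude 0.005 AU and
  a 0.1 Hz phase-diffusion linewidth (a fixed-frequency sinusoid would put
  all cardiac power into one bin and trip the power criterion, which real
  wandering heart rates do not); per-channel linear drifts (sd 10⁻⁴ AU/s);
  white (0.002 AU) and 1/f (0.001 AU) broadband noise; motion spikes as
  0.3–1 s attenuation boxcars of ±0.2 AU (≈13 μmol HbO₂-equivalent,
  comfortably above the rejection thresholds even after filter smearing)
  at 0.1/min per channel; dead channels (off by default) as 1000×
  light-starved intensity with ~50% multiplicative noise, which the CoV
  criterion catches with certainty.
- **Intensity**: per-channel baseline intensities are log-uniform on
  [0.1, 10]; I(t) = I₀·exp(−ΔA_total).
- Each participant draws from an independent substream of the master seed
  (`numpy.random.SeedSequence.spawn`), so cohorts are bit-reproducible and
  insensitive to participant order.

Not emulated: scalp/skull optics, systemic physiology beyond the
parameterized components (Mayer waves, respiration), spatially correlated
motion, infant fussiness (sessions always complete 20 trials). Passing
tests therefore demonstrate the *analysis* is correct and calibrated under
the stated noise model, not that it is robust to every artifact structure
of real infant data.

The default group scenario (`HemodynamicGroundTruth.scenario`) injects a
0.5 μmol spoken-over-signed advantage and a 0.6 μmol right-hemisphere
advantage in unimodal bilinguals. These are illustrative magnitudes for
exercising the statistics — no numeric effect sizes are available to fit —
and are parameters, not estimates.

## Numerical choices and degenerate inputs

- Threshold comparisons follow the stated wording: rejection requires
  *exceeding* a threshold (strict), participant exclusion requires *more
  than* 15 channels, the looking criterion requires *at least* 60%.
- Zero-variance t tests are flagged degenerate (p undefined unless the
  mean is also 0, in which case t = 0, p = 1).
- BH-FDR is computed by the step-up closed form; `m` may exceed the number
  of supplied p values (fixed at 46 for channel maps). It is order
  invariant but — like any step-up procedure — not idempotent.
- Accuracy differences are compared with a 10⁻⁹ guard because accuracies
  are k/(2n) rationals whose float differences carry last-ulp dust.
- `peaks.tsv` is written with `%.17g` and read with
  `float_precision="round_trip"` so resumed pipeline runs are
  bit-identical to uninterrupted ones.

## Problem sizes used in the validation suite

Simulation-backed checks use cohort sizes chosen to estimate each quantity
with adequate Monte-Carlo precision: 200 pure-noise cohorts of 20
participants for chance-level calibration; 200 cohorts × 200 permutations
for the type-I error of the permutation test (binomial 95% check around
α = 0.05); 20 participants for the ±20% peak-recovery check; 100
simulations for the per-group lateralization power check (d = 1.5,
n = 18); 500 simulations for the ANOVA p-uniformity check.
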