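# Methods

## The measurement and task model

The pipeline assumes a continuous-wave NIRS array of 16 channels on the
forehead (6 × 2 probe matrix, 3.0 cm emitter–detector separation, channel
9 on Fpz, bottom probe corners near F7/F8 in the 10–10 system), sampling
oxy-Hb concentration change every 650 ms. Channels 1–4 form the right-DLPFC
ROI and channels 13–16 the left-DLPFC ROI; channel ids are 1-based at every
interface. Units of oxy-Hb change are arbitrary throughout — the pipeline
is linear in the signal, so no instrument scale is assumed.

The session is a fixed block design: a Repeat section (0–40 s, 4 trials),
a Reverse section (40–100 s, 6 trials), and a second Repeat section
starting at 100 s with 8 trials, all at a 10 s stimulus-onset asynchrony
(18 trials total). Eight trials at 10 s spacing need 80 s, so the second
Repeat section is modelled as 100–180 s while the analyzed recording spans
only the first 160 s (246 samples at 0.65 s); every analysis window — the
baseline anchors [30, 40) s and [150, 160) s and the dependent-variable
window [90, 100) s — lies inside the recorded span, and the tail of the
final section is simply never used by the hemodynamic analysis.

## Preprocessing

**Low-pass filter.** A brick-wall filter in the discrete Fourier domain:
real FFT per channel, every bin with frequency strictly above 0.05 Hz set
to zero, inverse FFT. The brick wall is chosen over an FIR/IIR design
because it is exactly linear, exactly idempotent, and preserves DC — all
three properties are asserted to 1e-10 in tests. Edge ringing from the
sharp cutoff is tolerated because the two-anchor baseline correction
downstream absorbs residual slow structure.

**ICA artifact rejection.** The skin-blood-flow artifact is modelled as a
source that loads on *all* channels with the same sign and similar
magnitude (autonomic innervation of the scalp is not spatially localized),
whereas task activation is confined to frontal ROI channels. FastICA
(fixed-point, whitened, 16 components, deterministic per seed) decomposes
the recording; a component is classified as global when its mixing column
has (a) all entries of one sign and (b) uniformity `min|w| / max|w| ≥ τ_u`
with default τ_u = 0.25. At most 3 components are excluded (matching the
1–3 exclusions typical of visual screening); if more qualify, the most
uniform are kept. Per-component scores are written to an audit table so a
human can review what an inspector would have seen.

Two deliberate orderings differ from the naive "filter, then ICA"
sequence:

- **ICA runs on the broadband signal, before the low-pass.** A brick-wall
  0.05 Hz filter of a 160 s recording leaves ≈ 17 effective temporal
  degrees of freedom per channel. Estimating a 16 × 16 unmixing rotation
  from so few effective samples is statistically hopeless and the
  whitening step becomes near-singular; measured on synthetic data, ICA
  after filtering recovers nothing. On broadband data the strong
  non-Gaussian sources separate cleanly. `filter_first=True` restores the
  literal order for comparison.
- **Non-convergence is routine and non-fatal.** Most whitened dimensions
  contain near-Gaussian sensor noise with no stable fixed point, so the
  full FastICA iteration rarely "converges" even when the artifact and
  task sources are extracted perfectly. The decomposition retries up to 3
  seeds, then returns the last solution with `converged=False`
  (`on_fail="raise"` makes it strict). Reconstruction is exact regardless,
  because the model is linear either way.

**Reconstruction.** `mixing[:, keep] @ sources[keep] + channel_means`.
Excluding nothing reproduces the input to < 1e-8 (max abs).

## Hemodynamic summarization

Baseline correction subtracts, per channel, the straight line through the
two anchor points `(mean time, mean signal)` over [30, 40) s and
[150, 160) s. Using the anchor *means* as the two interpolation points
makes the corrected anchor-window means exactly zero and the operation
idempotent; a least-squares-over-anchor-samples variant is available via
`least_squares=True`. Samples are attributed to windows by half-open
`[start, end)` intervals on the timestamp grid `t0 + k·0.65 s`.

The laterality index is `LR = mean(L-ROI) − mean(R-ROI)` of per-channel
window means over [90, 100) s — the last 10 s of the Reverse section,
where the block response has plateaued. A `full-reverse` window option
([40, 100) s) exists for sensitivity analysis. `LR` is linear in the data
and antisymmetric under swapping the ROI sets; both are property-tested.

## Behavioral scoring

Morae are opaque tokens; a Repeat response is correct iff it equals the
stimulus token-by-token, a Reverse response iff it equals the reversed
stimulus (a palindrome answered verbatim is therefore correct). Response
time is `(response_end − stimulus_onset)·1000` ms; absent responses are
incorrect with undefined RT, and mean correct RT is computed over correct
trials only, pooling both Repeat sections. Participants with no correct
trial in a condition get a missing mean, never a silent drop.

## Inference

**Mixed ANOVA.** Classical split-plot partition for one between-subjects
factor crossed with a complete 2-level within-subjects factor, with
weighted marginal means (verified against pingouin for balanced and
unbalanced groups, and against a naive loop-based SS decomposition).
Degrees of freedom for k groups and N subjects: group (k−1, N−k),
location (1, N−k), interaction (k−1, N−k). With two within levels
sphericity holds trivially, so no correction is applied. The same routine
serves the group × condition ANOVA on response times and the 2 × 2
accuracy × location control analysis. A scale-aware guard treats SS below
1e-12 of the total as zero so that degenerate inputs (identical within
levels) yield F = 0 rather than a 0/0 artifact.

**Simple effects.** The per-group L-vs-R contrast is the paired t test
reported as F(1, n_g−1) = t².

**Scheffé.** For each pair, F* = t²_pair/(k−1) using the pooled MS error,
referred to F(k−1, N−k). With k = 2 this reproduces the omnibus p exactly.

**Moderated regression.** Both predictors are centered on their sample
means; step 1 enters age and LR, step 2 adds their (centered) product.
Raw coefficients come from OLS (statsmodels); standardized β uses
b·SD(x)/SD(y) with the product term standardized by the SD of the centered
product — a convention that must be stated because reported βs are not
comparable across conventions. ΔR² is tested with
F = (ΔR²/q)/((1−R²₂)/(n−p₂−1)). Simple slopes of age at moderator value
m = ±1 SD are b₁ + m·b₃ with variance Var(b₁) + m²Var(b₃) + 2m·Cov(b₁,b₃)
on the step-2 residual df; a re-centered-refit oracle checks both the
point estimate and the SE to 1e-10. All p-values are two-sided; no
correction beyond Scheffé is applied.

## The synthetic cohort generator

Each channel is `a_c·r(t) + global_amp·g_c·s(t) + ε_c(t)`:

- `r(t)` is a boxcar over the Reverse section convolved with a canonical
  double-gamma HRF (peak 6 s, undershoot 16 s, dispersion 1 s, undershoot
  ratio 1/6, unit peak). The convolution is evaluated *in closed form*
  via gamma CDFs at the sample times, so with noise disabled the pipeline
  L–R index equals the closed-form windowed value to 1e-9 — an exact
  end-to-end recovery check, not an approximate one. Note the plateau of
  `r` equals the HRF integral (≈ 5.2 for the defaults), so measured ROI
  means are that factor above the nominal amplitudes.
- `a_c` is `amp_left` on L-ROI channels, `amp_right` on R-ROI channels,
  their midpoint elsewhere. Group defaults: Low 0.60/0.60 (bilateral,
  immature), Middle 0.60/0.08 and High 0.70/0.08 (left-dominant), with
  between-participant SD 0.12 on the left amplitude. The right-side
  amplitudes sit well below τ_u × amp_left so that the task component's
  mixing column fails the uniformity criterion with margin; this makes
  the planted lateralization stronger than real cohorts show, which is
  why synthetic F statistics are much larger than typical empirical ones.
  For bilateral (Low) participants the task component *is* spatially
  uniform and is legitimately removed by the classifier — a real,
  documented confound of spatial-uniformity-based rejection; it does not
  bias the L–R index, which cancels uniform signal.
- `s(t)` is the skin-blood-flow artifact: one very-low-frequency
  vasomotor tone per participant, frequency drawn U(0.025, 0.045) Hz,
  random phase, unit SD, with positive loadings `g_c` of CV 0.04. The
  band sits *below* the 0.05 Hz cutoff deliberately: the filter cannot
  remove it, so ICA rejection is consequential. A single tone is used
  because FastICA on 246 samples fragments composite waveforms (sums of
  sinusoids, Gaussian random walks) across components; a lone tone is
  strongly sub-Gaussian and is isolated essentially always (measured
  flag rate 100/100 on lateralized participants, false-flag of the task
  component ≈ 1%).
- `ε` is i.i.d. Gaussian sensor noise, SD 0.2.

Response times follow
`RT = b₀ + b_age·age_c + b_lr·LR_c + b_int·age_c·LR_c + u + e` with
`age_c`, `LR_c` centered at declared population means (118.5 months,
0.37), a participant-level residual u (SD 1000 ms) and small per-trial
jitter e (SD 150 ms); Repeat trials are N(1900, 220) ms and always
correct; Reverse accuracy is Bernoulli with logit 2.4 + 0.045·age_c.
Defaults b₀ = 3300, b_age = −27 ms/month, b_lr = −400 ms/unit,
b_int = −65 ms/(month·unit) were derived analytically to give
standardized coefficients near (−0.45, −0.10, −0.25), group mean Reverse
RTs ordered Low > Middle > High in the 2.2–3.7 s range, ~80% power for
the interaction at n = 103, and ≥ 99% sign recovery. Splitting the
residual into a dominant participant-level term plus small trial jitter
keeps the participant-level regression homoscedastic (the jitter
contributes ≤ 1% of residual SD), so 95% CIs cover the planted
coefficients at nominal rate.

Ages are uniform over 84–153 months by default (a stratified option
fills the three two-year groups evenly); groups follow the
completed-years rule Low [84, 108), Middle [108, 132), High [132, 156).
Everything emitted — recordings, logs, the truth file — is a pure
function of `(config, seed)`, byte-for-byte.

**What the generator does not emulate:** motion spikes, heartbeat and
respiration bands, optode-coupling drift, deoxy-Hb, spatially
*structured* (non-uniform) systemic physiology, age-correlated artifact
levels, and realistic (weak) laterality effect sizes. Passing tests
therefore demonstrate correctness of the algorithms under the stated
model, not robustness of ICA-based rejection on arbitrary real data.

`simulate_behavioral_cohort` is a vectorized participant-level shortcut
of the same behavioral model (identical in distribution to scoring the
trial-level logs) used for Monte-Carlo studies with thousands of
replicate cohorts.

## Problem sizes and numerical tolerances

The test suite and acceptance script use: 100 simulated participants for
ICA operating characteristics, 2000 (tests) / 1000 (script) replicates
for the type-I calibration, 400 replicates for sign recovery and CI
coverage, and one full 103-participant cohort for the end-to-end
pipeline run — sizes at which the Monte-Carlo bands (e.g. type-I in
[0.04, 0.06]) are informative while the whole suite runs in minutes on
one CPU. Exactness checks use 1e-9 (baseline/laterality closed form),
1e-8 (ICA round trip, OLS vs normal equations), 1e-10 (filter linearity,
paired-t identity, simple-slope refits) and 1e-12 (Scheffé closed form).

## Known limitations

- The uniformity criterion cannot distinguish a genuinely bilateral
  cortical response from systemic physiology; only laterality-based
  conclusions are protected (by cancellation), not absolute ROI levels.
- Sixteen-component ICA on ~250 samples is at the edge of
  identifiability even broadband; classification quality degrades
  gracefully (components fragment and fall below τ_u) rather than
  failing loudly.
- The two-anchor baseline assumes the signal returns to baseline within
  the final anchor window; sustained post-block activity would bias the
  correction.
- The moderated regression treats the measured L–R index as error-free;
  with measurement noise the coefficients are attenuated relative to the
  planted values (the recovery guarantees are stated for the planted
  regressor).
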