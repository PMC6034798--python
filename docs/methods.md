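# Methods

This note documents the models, estimators and numerical choices behind
the package, in the spirit of the methods documentation that accompanies
simulation and statistics toolkits: what is assumed, what is calibrated,
what the defaults mean, and what passing the test suite does and does not
demonstrate.

## Forward model

**Transmit waveform.** The probe signal is a continuous multitone over
the whole record,

    s(t) = Σ_k A_k sin(2π f_k t),    k = 1 … n,

with `n = 10` components uniformly spaced over 0.7–2.0 MHz (spacing
Δf ≈ 0.1444 MHz) and integer amplitudes `A_k ∈ [1, 255]`.  Whether the
physical instrument transmits a continuous multitone or repeated bursts
is an open question; the phase-based description of the measurement is
compatible with either, and the continuous form makes every window of
the record informative.  The default sampling rate is 25 MHz (12.5× the
top component); a hard floor of 5× the top component is enforced.
Records last 30 s and are analysed in 10 s windows in the clinical
protocol.

**Medium.** The head path is a single homogeneous segment of length `L`
with

- linear phase-velocity dispersion `c(f) = c₀ + s·(f − f_ref)`,
  `f_ref = 1.35 MHz` (band centre).  Dispersion in brain tissue is real
  but weak and no functional form is established at these bandwidths;
  linearity is the minimal model that produces the observed
  frequency-ordered arrival times.
- power-law attenuation `α(f) = α₀ (f/1 MHz)^γ` in Np/m, the standard
  soft-tissue model, with `α₀ ≥ 0`, `γ ≥ 0`.
- additive white Gaussian noise specified as an SNR in dB relative to
  received signal power (`None` = noiseless).

Propagation is applied per component — a delay `t_k = L/c(f_k)` as an
exact phase shift and a scale `exp(−α(f_k)L)` — so simulated ground
truth is exact rather than resampled.  By default samples before a
component's arrival are zeroed (`onset=True`): the onset edge is the
only feature of a periodic multitone that carries *absolute* timing, and
analysis windows are simply placed after a settle margin so that the
post-onset waveform remains an exact shifted sinusoid.

**Transmit pre-emphasis and quality.** Component amplitudes can be
pre-emphasized deterministically (`∝ exp(+α(f_k)L)`, peak at 255,
integer-rounded) so expected received energies equalize.  The record
quality score is the smaller of the band-integrated received powers at
the two extreme components divided by a reference power (the transmitted
band power, or the expected received power during cohort simulation),
clipped to [0, 1]; records are accepted above 0.70.  The exact reference
and integration bandwidth of the instrument's quality display are not
public; the implementation fixes them as the half-spacing band around
each extreme component.

## Estimation pipeline

**Spectral decomposition.** Component frequencies are known exactly, so
amplitude/phase recovery is linear: ordinary least squares on the
cos/sin design, solved through chunk-accumulated normal equations (a
window never needs to be materialized as a dense design matrix) with a
Cholesky solve.  Phase convention: a pure `sin(2πft + φ)` yields phase
`φ`; the time basis is the record clock, so transmit/receive phase
differences are window-independent.  The residual RMS is computed by an
explicit second pass over the window; the one-pass quadratic-form
identity cancels catastrophically on near-noiseless data.  A polyphase
decimation helper is provided for long records; tests and the cohort
simulator instead use short records directly (below).

**Coarse absolute delay.** A continuous multitone is periodic (≈90 µs
for the default grid), and its correlation function additionally has
full-height grating lobes every `1/Δf ≈ 6.9 µs` and strong
number-theoretic near-recurrences, so plain cross-correlation cannot
give an absolute delay.  Two estimators are provided:

- *Matched onset filter* (transmitted record available): maximize
  `|C(τ)| − E(τ)/2`, where `C` is the correlation of the received record
  with the *analytic* transmitted template (its magnitude is the
  carrier-free envelope) and `E(τ)` the template energy overlapping the
  record — the Gaussian maximum-likelihood onset statistic.  Competing
  envelope lobes differ by ~1%, so each candidate lobe is first refined
  to sub-sample precision by parabolic interpolation; without this, a
  lobe that happens to land on the sample grid can beat the true lobe
  sitting between samples.  Monte Carlo at 0 dB SNR (2.2 ms records):
  RMS error ≈ 2.5 ns, 100% of 500 trials within half a cycle of the
  lowest component.  Noiseless delays are recovered to one sample.
- *Onset changepoint* (no reference): short-time block powers are
  smoothed over `1/Δf` (cancelling the multitone beat pattern exactly),
  a cumulative-sum changepoint locates the step, and a least-squares
  known-width ramp fit pins the onset.  Accurate to ~0.1 µs at the
  cohort's 30 dB SNR; used by the bulk extraction pipeline where the
  needed accuracy is only half a period of Δf (~3.5 µs).

**Time of flight.** Each wrapped transmit–receive phase difference fixes
`t_k` only modulo `1/f_k`.  Integer cycles are resolved in three stages
of decreasing wavelength: (1) the coarse onset delay anchors (2) the
adjacent-pair "synthetic wavelength" — wrapped phase differences between
neighbouring components measure the delay modulo `1/Δf` and refine the
anchor to the ~10 ns scale — and (3) per-component resolution proceeds
sequentially in ascending frequency, each component seeded by its
predecessor, so band-wide dispersion (~0.2 µs between extreme
components at the calibrated targets) never approaches the 0.4-cycle
residual gate.  A single shared seed for all components would leave only
~0.06 cycles of margin at 2 MHz under the same dispersion.  Residuals
above the gate raise an ambiguity error rather than returning a silently
wrong cycle count.

The per-exam scalar ToF estimate (used in the precision studies) is the
inverse-variance weighted mean over components: at fixed phase noise the
time error scales as `1/f`, so weights are `f²`.

**Attenuation and FFT features.** Attenuation is reported as fractional
amplitude loss `ATT_k = 1 − A_rx,k/A_tx,k ∈ [0, 1]` — unitless, monotone
in physical attenuation, and in the published value range; the absolute
scale of the instrument's attenuation output is not documented, so the
cohort generator is calibrated in this same convention and no claim is
made of matching the device scale.  FFT features are Parseval-normalized
band energies in the half-spacing band around each component plus the
power-weighted spectral centroid over the pulse band; which FFT features
the original analysis used is not stated, so these are a declared
stand-in.  Per-exam aggregation is the component-wise median over all
windows of all three records (mean available as an option; the source
description is ambiguous between the two and the median is the more
specific claim).

**Derived acoustics.** `c_k = L/t_k`, band-average `c̄`, bulk modulus
`K = ρ_ref c̄²` with `ρ_ref = 1040 kg/m³` (standard brain-tissue
density), and the constant-K linearization `dρ/ρ = −2 dc/c` for the
density sensitivity.  With `dc = 1.25 m/s` at `c = 1540 m/s` this gives
`|dρ/ρ| = 1.6×10⁻³`.  The path length for derived quantities defaults
to `0.85 × circumference/π` (a temporal-window chord); only derived
acoustics, not the ToA/ATT features themselves, depend on it.

## Synthetic cohorts

No raw clinical recordings are public, so the cohort module generates
the study conditions: 75 hypertensive and 22 non-hypertensive subjects,
three records each, binary covariates at the published per-group rates
(CAD, diabetes, smoking, family history, …), age ~ N(66, 6)/N(64, 8)
years and head circumference ~ N(57, 2) cm.

Per-subject latents are the three calibration rows of the published
feature summary: band-centre transit time (component 6) and fractional
attenuation at components 4 and 10, drawn from group-specific normals
with the published means and SDs.  The two attenuation latents have
correlation `0.8^|10−4|` (an AR(1)-in-component-index model with
adjacent correlation 0.8; correlations between per-frequency features
are otherwise induced physically by the smooth medium law).  Latents are
redrawn until admissible (`0 < ATT₄ < ATT₁₀ < 1`, required by `γ ≥ 0`);
this truncation shifts the realized moments slightly.  Transit-time
variance is split 50/50 between head-size variation (shared with the
sampled circumference) and intrinsic velocity variation.  The latent
values are inverted into a medium (`c₀`, dispersion slope from the
group-level ToA-vs-frequency slope, `α₀` and `γ` from the two ATT
targets), and the subject's stored ground truth is the medium-implied
per-frequency profile, making the calibration round trip exact.  The
attenuation row at component 9 is model-implied rather than separately
matched — a two-parameter power law cannot interpolate three rows.

`effect_scale` multiplies every between-group mean difference about its
midpoint: 0 gives an exchangeable null cohort, 1 the published
separation (latent Mahalanobis distance ≈ 0.58), and
`effect_scale_for_mahalanobis(config, 3.0)` (≈ 5.2) a strongly separated
cohort.  Because the group signal lives in the medium, every downstream
number — features, tests, classifier — reflects the full pipeline.

**Record geometry.** Full-protocol records (30 s × 25 MHz = 7.5×10⁸
samples) are supported by the streaming estimators but are impractical
for simulation studies.  `CohortConfig.short_records()` is the
package's standard desk-scale geometry: 3.2 ms records at 10 MHz with
1 ms windows after a 0.2 ms settle margin, at 30 dB SNR.  The choice is
driven by phase-noise arithmetic: with N = 10⁴ samples per window the
per-component phase SE is ~10⁻³ rad, i.e. ~0.2 ns of ToF noise and
~0.1% amplitude noise — four orders of magnitude below the
between-subject spreads being modelled — so cohort-level feature
distributions are indistinguishable from the full-length protocol.

**What the generator does not emulate.** Skull refraction and
transducer-coupling variability, physiological non-stationarity within a
record, non-Gaussian or structured interference, device-specific
offsets in absolute ToA, and any within-subject correlation structure
beyond the shared medium.  Passing tests therefore demonstrates the
estimators' correctness and calibrated statistical behaviour under this
generative model, not clinical performance on real recordings — the
published classification accuracy on the clinical cohort is explicitly
not reproducible from synthetic data, and the classifier checks instead
bracket behaviour (chance-level AUC on null cohorts; AUC ≥ 0.9 at a
configured 3σ separation).

## Statistics and classification

Fisher's exact test is the two-sided probability-mass ordering (sum of
hypergeometric probabilities ≤ that of the observed table, with the
customary 1+10⁻⁷ relative slack) — the convention of R's `fisher.test`,
which reproduces all published contingency p-values at their printed
precision.  Kruskal–Wallis uses mid-rank ties with tie correction and
the χ² approximation (standard at n = 22/75); the degenerate all-equal
case returns (H, p) = (0, 1) by convention.  p-values are printed to two
significant figures in reports, kept at full precision internally; no
multiple-testing correction is applied, matching the original analysis.

Classification is per subject (one exam-aggregated feature vector each),
which makes cross-validation leakage-free by construction.  Features are
z-scored with training-fold statistics only (constant features map to
zero with a logged warning).  The model is a gradient-boosted tree
ensemble — 200 trees, learning rate 0.05, depth 3, subsample 0.8,
conventional defaults at n ≈ 100 since the original hyperparameters are
unpublished — evaluated by 10 × stratified 5-fold CV; out-of-fold scores
are averaged per subject across repeats and a single ROC is swept over
the averaged scores (trapezoidal AUC, equivalent to pair concordance
with half credit for ties).  The operating point is Youden's J unless a
fixed threshold is configured.  Everything is bit-reproducible for a
fixed seed.

## Numerical choices and degenerate inputs

- OLS via normal equations is adequate here: the multitone design over
  thousands of cycles is near-orthogonal (condition number ~1), so no QR
  of the full design is needed.
- Integer-cycle residual gate: 0.4 cycles at every resolution stage;
  exceeding it raises rather than guessing.
- Zero-delay records return a coarse delay of exactly 0 (the changepoint
  significance gate treats a stepless power profile as onset-at-start).
- Attenuation estimates are clipped to [0, 1]; a zero transmit amplitude
  is a validation error, as are duplicate fit frequencies (rank-deficient
  design), windows shorter than twice the basis size, components at or
  above Nyquist, empty groups in rank tests, negative contingency
  counts, and single-class classification labels.
- Medium validation requires positive `L` and `c` over the band and
  non-negative `α₀`, `γ`; infeasible calibration targets (loss
  decreasing with frequency) raise a calibration error naming the
  constraint.

## Monte-Carlo precision studies

`acg.precision.tof_precision_study` simulates records with a known
sub-sample delay (97.4026 µs: 15 cm at 1540 m/s) and calibrates the
white-noise level so the lowest component's phase standard error is 1°
(`σ_n = σ_φ A √(N/2)`, the OLS phase-error relation).  Across 100
replicates the combined ToF estimate has RMS error ≈ 0.5 ns and the
implied speed-of-sound RMS error ≈ 0.008 m/s — comfortably inside the
instrument-level figures of 5.6 ns and 1.25 m/s, as expected: a single
component at 0.7 MHz with 1° of phase error on both ends already
accounts for ≈ √2 × 1°/(2π·0.7 MHz) ≈ 5.6 ns, and combining ten
components with f²-weighting reduces it several-fold.

## Known limitations

- Single-segment homogeneous path: no skull/tissue layering, no
  refraction, no beam geometry.
- Linear dispersion and two-parameter power-law attenuation cannot
  reproduce arbitrary per-frequency profiles (e.g. the third published
  attenuation row is implied, not matched).
- The onset-based absolute delay assumes the record begins before the
  signal arrives; a steady-state-only record has no absolute timing
  information.
- The quality score's reference convention is internally consistent but
  not verified against the instrument's display.
- Synthetic cohorts are a model of the published summary statistics, not
  of raw clinical data; classifier results on them bound sanity, not
  clinical accuracy.
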