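# Methods

`eislope` estimates the aperiodic ("fractal", 1/f^β) exponent of
resting-state EEG as a proxy for the cortical excitation/inhibition (E/I)
ratio, treats the spectrum as **bimodal** — one exponent β_lo in 1–4 Hz,
one exponent β_hi in 20–45 Hz, with the 4–20 Hz range (alpha/beta peaks,
knee region) excluded from fitting — and resolves both **in time** over
sliding windows. Each subject is summarized by the temporal mean μ(·) and
temporal standard deviation σ(·) of the windowed exponents, aggregated over
resting-state networks (RSNs), and a normality-gated statistical battery
compares groups and relates features to clinical scores.

## Pipeline

1. **Preprocessing** (`eislope.preprocess`). Drop nine predesignated
   channels (seven noisy scalp sites plus the M1/M2 mastoids; 64 → 55),
   polyphase-resample to 256 Hz (anti-alias FIR included), band-pass
   0.5–100 Hz with a 4th-order Butterworth applied forward–backward (zero
   phase; effective 8th-order magnitude — the printed "4th order
   zero-phase" is read as the design order), notch 50/100/150 Hz
   (second-order IIR, Q = 30, zero phase; notches at or above the
   post-resampling Nyquist are skipped with a warning — a 150 Hz notch
   cannot apply at 256 Hz), common average reference, and a seeded random
   30-s contiguous epoch. ICA/MARA artifact removal is out of scope; an
   `ica_hook` accepts externally cleaned data. Synthetic recordings are
   generated at the target rate, full-band and artifact-free, so the
   synthetic pipeline applies only referencing and epoch selection.
2. **Windowing.** The 30-s epoch is divided into 8-s windows with 75%
   overlap (2-s step → 12 windows). Window count is
   `floor((T − w)/s) + 1`; a trailing remainder is left unanalyzed.
3. **IRASA** (`eislope.irasa`). Per window and channel, the Hann-tapered
   periodogram is computed on a 0.0625 Hz grid (an 8-s epoch has 0.125 Hz
   natural resolution, so the printed grid implies two-fold zero-padding;
   Welch sub-averaging is rejected to preserve the grid). For each
   rescaling factor h ∈ {1.1, …, 2.6} the signal is resampled by h and 1/h,
   the pair's auto-spectra are geometric-mean-combined, and the fractal
   spectrum is the (conventional, mean-of-central-values) median across the
   16 factors; `oscillatory = mixed − fractal` exactly. The configuration
   asserts `fs ≥ 2·f_max·h_max` (256 ≥ 234) at validation time.
4. **Slopes** (`eislope.slopes`). OLS of log10(fractal power) on
   log10(frequency) in 1–4 (β_lo), 20–45 (β_hi), and 1–45 Hz (β_bb,
   control), band edges inclusive; β is reported as |slope|. Channel slopes
   are averaged within RSNs per window (channel-average first, temporal
   statistics second), then μ and σ (sample SD, n−1) are taken over the 12
   windows.
5. **Statistics** (`eislope.stats`). Lilliefors (KS with estimated
   parameters; statsmodels table p-values) gates every contrast at
   α = 0.05: pooled-variance Student t vs Mann-Whitney U for group
   comparisons (pooled, not Welch, to match a df = 59 convention for
   31 + 30 subjects; U exact for n₁+n₂ ≤ 12, otherwise normal
   approximation with tie and continuity correction), paired t vs Wilcoxon
   signed rank for the per-channel β_lo/β_hi bimodality contrast (gated on
   the differences). Benjamini–Hochberg FDR families: the 55 per-channel
   bimodality tests per group, and the 6 networks per measure × band.
   Clinical correlations residualize both variables on age, sex (0/1),
   education, illness duration, and chlorpromazine-equivalent dose by OLS,
   then use Pearson/Spearman by the same gate; they are deliberately not
   multiplicity-adjusted (exploratory).

## Resampling engines

Three interchangeable IRASA resampling engines are provided and tested for
agreement (band-slope differences ≲ 0.01):

- `poly` (default): rational polyphase `resample_poly` with anti-aliasing.
- `fourier`: ideal sinc resampling via FFT.
- `spectral`: the closed form of ideal resampling — a Hann taper scales
  with the signal, so the tapered periodogram of an ideally stretched
  signal equals the original periodogram with a rescaled frequency axis.
  One fine-grid (4× oversampled) float32 periodogram per epoch yields all
  h pairs by interpolated lookup, ~20× faster; Monte-Carlo validation runs
  use it.

## Synthetic world

The generator (`eislope.synth`) is phenomenological: spectral synthesis
(target amplitude spectrum f^(−β/2), uniform random phases, inverse FFT),
giving exact control of spectral shape; no biophysical E/I model is
implied. A recording's target spectrum is a continuous piecewise power law
(β_lo below a knee at 10 Hz, β_hi above — the knee is confined to the
excluded 4–20 Hz band) plus a Gaussian alpha bump. Temporal dynamics: one
β_hi draw from Normal(β_hi, beta_hi_sd) per 2-s window step, shared across
channels (a global, arousal-like fluctuation), segments joined with
equal-power cosine cross-fades of half a step; `beta_hi_sd = 0` synthesizes
the whole duration in one piece. Defaults state the emulated study's
conditions: 55 channels (packaged 10-10 montage, so RSN mapping applies
unchanged), 256 Hz, 30 s, β_lo = 1, β_hi = 2, unit-free peak at 10 Hz.

**Alpha bump default (height 2× the aperiodic floor at 10 Hz, FWHM 1 Hz).**
IRASA's known smearing artifact spreads a peak at f0 over [f0/h_max,
f0·h_max] — up to 26 Hz here — and a stronger or broader alpha (3–5×, 2 Hz
FWHM) measurably steepens β̂_hi (+0.2 to +0.44 in our measurements),
contradicting the premise of the emulated analysis that its h-range and
band choices leave high-band slopes unbiased by alpha. The default
therefore sits at the moderate end of realistic resting alpha; the residual
bias at the default is ≈ +0.14 and the bias curve versus peak height and
bandwidth is a documented limitation of the method, not of the generator.

**Calibration of σ targets.** Cohort specifications state group means and
the between-subject SD of σ(β_hi) on the *measured* scale (the scale group
statistics are reported on: means 0.1264 and 0.0955; pooled SD 0.044
recovered from t₅₉ = 2.7353 via d = t·√(1/n₁ + 1/n₂)). Measured σ is an
attenuated, noise-floored function of the generative `beta_hi_sd`: each 8-s
window averages four segment draws, and the slope-estimation noise alone
produces σ ≈ 0.052 at the dorsal-attention (DA) network level. The mapping
was measured once (48 frozen seeds per grid point; reference configuration:
9 DA channels, CAR, 30 s, 8 s/75% windows, spectral engine) and frozen as a
monotone interpolation table in `synth.py`; targets are inverted through
it, and requested between-subject SDs are deconvolved of the measured
per-subject estimation noise (SD ≈ 0.028) so that the measured spread, not
the latent one, matches the request. Simulated positive-symptom scores are
drawn via a Gaussian copula (Pearson ρ_g = 2·sin(πρ/6)) against the
subject's σ target, scaled to a PANSS-positive-like distribution
(14.63 ± 5.12, clipped to [7, 49]). Other demographics are decorative
draws matched to published clinical-cohort summary statistics and are not
calibrated.

**What a green test does not establish.** The generator contains no
artifacts, no volume-conduction channel correlations (channels are
independent given the shared exponent sequence), no non-stationary alpha,
and no subject-specific spectral idiosyncrasies; recovery results certify
the estimation pipeline on its stated world, not performance on real EEG.

## Numerical choices and degenerate cases

- Spectral synthesis uses deterministic amplitudes with random phases; DC
  is zero (signals are exactly zero-mean), and the Nyquist bin is made
  real.
- The fractal *level* from median-of-geometric-means sits ~25–30% below
  the mixed spectrum for single-periodogram epochs (the median of skewed
  bin distributions lies below the mean), so the raw oscillatory component
  is positive broadband; band slopes — the quantities of interest — are
  unaffected (the offset is a constant factor). Oscillatory peak location
  should therefore be read from the fractal-normalized oscillatory
  spectrum.
- Slope fits require ≥ 3 in-band bins and strictly positive fractal power;
  r² is clipped to [0, 1].
- Paired contrasts: all-zero differences → statistic 0, p = 1; constant
  non-zero differences → ±∞ t, p = 0, flagged as degenerate.
- Gating with n < 4 or constant data cannot assess normality and falls to
  the non-parametric branch, recorded in the result's `branch` field.
- Truncations: per-subject σ targets are redrawn until positive;
  per-segment β_hi draws are clipped at 0.
- Seed fan-out uses `numpy.random.SeedSequence` spawning; per-subject
  epoch seeds are derived from SHA-256 of (global seed, subject id), so
  stages can be re-run in isolation.

## Known limitations

- The Lilliefors gate has limited power at moderate n (≈ 0.63 against
  Uniform(0,1) at n = 100, Monte-Carlo), so the parametric branch will
  sometimes fire on non-normal data; the branch is recorded per test.
- IRASA low-band estimates use down-rescaled content below the 0.5 Hz
  high-pass edge of real recordings (1 Hz / 2.6 ≈ 0.38 Hz); synthetic data
  are full-band, so this bias affects only filtered real data.
- The channel→RSN map matches the published per-network counts (VN 12,
  SM 10, DA 9, VAL 12, FP 6, DMN 6) but individual assignments are a
  best-effort scalp projection; the map is an editable two-column text
  file.
- EDF I/O is a minimal 16-bit implementation (integer sampling rates,
  whole seconds); BrainVision/FIF need the optional `mne` extra.
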