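"""Synthetic resting-state EEG with controlled spectral-slope structure.

The generator is phenomenological: signals are built by spectral synthesis
(target amplitude spectrum, independent uniform random phases, inverse FFT),
which gives exact control over the spectral shape. A recording's target
spectrum is a bimodal power law — exponent ``beta_lo`` below a knee
frequency and ``beta_hi`` above it, continuous at the knee — plus an
optional Gaussian oscillatory bump (the alpha peak). Temporal E/I dynamics
are emulated by drawing a fresh high-band exponent per 2-s segment (one per
sliding-window step) from Normal(beta_hi, beta_hi_sd) and cross-fading
segments with equal-power cosine ramps; the draw sequence is shared across
channels (a global, arousal-like fluctuation), while phases are independent
per channel.

Cohorts reproduce the targeted clinical-cohort structure: two groups whose *measured*
temporal variability of the high-band slope, sigma(beta_hi) over the dorsal
attention (DA) network, differs in mean but not in mu(beta_hi), plus a
simulated positive-symptom score rank-correlated with the variability in
the patient group. Group means and the between-subject SD are specified on
the measured scale (the scale cohort statistics are reported on), so the
generator inverts a fixed, pre-measured calibration (see the ``_SIGMA_*``
constants) to obtain generative ``beta_hi_sd`` values.

Every generator is a pure function of (spec, seed).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import InvalidArgumentError, Recording
from .montage import RETAINED_55

# --- calibration table -----------------------------------------------------
# Measured once with frozen seeds (48 per grid point) for the reference
# analysis configuration: 9 DA channels, common average reference, 30-s
# segment, 8-s windows at 75% overlap, default IRASA settings, 'spectral'
# engine. _SIGMA_CAL_MEAN[i] is the mean measured DA-level sigma(beta_hi)
# when the generative window-to-window SD is _SIGMA_CAL_S[i]; the curve has
# an estimation-noise floor (~0.052 at s = 0) and is attenuated relative to
# s because each 8-s window averages four 2-s segment draws. Targets on the
# measured scale are inverted through monotone interpolation of this table.
# _SIGMA_MEAS_SD is the subject-to-subject SD of measured sigma at fixed s
# near the cohort operating points (s ~ 0.13-0.19); cohort between-subject
# SDs are deconvolved with it so that the *measured* spread matches the
# requested value.
_SIGMA_CAL_S = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.40)
_SIGMA_CAL_MEAN = (0.0519, 0.0536, 0.0771, 0.1042, 0.1328, 0.1620, 0.1917, 0.2517)
_SIGMA_MEAS_SD = 0.028


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic recording.

    beta_lo / beta_hi: target spectral exponents below / above knee_freq.
    knee_freq: transition frequency, constrained to the 4-20 Hz band that is
        excluded from slope fitting.
    peak_*: Gaussian oscillatory bump; peak_height is the peak's power
        relative to the fractal floor at peak_freq (0 disables it),
        peak_bandwidth is its FWHM in Hz.
    beta_hi_sd: window-to-window SD of the high-band exponent (generative
        scale; 0 yields a stationary recording synthesized in one piece).
    window_seconds / window_overlap: the sliding-window scheme the dynamics
        are laid out for; segments are one window-step (2 s) long.
    """

    n_channels: int = 55
    fs: float = 256.0
    duration: float = 30.0
    beta_lo: float = 1.0
    beta_hi: float = 2.0
    knee_freq: float = 10.0
    peak_freq: float = 10.0
    peak_bandwidth: float = 1.0
    peak_height: float = 2.0
    beta_hi_sd: float = 0.19
    seed: int = 0
    window_seconds: float = 8.0
    window_overlap: float = 0.75
    channel_labels: tuple[str, ...] | None = None
    rms_uv: float = 10.0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise InvalidArgumentError("n_channels must be >= 1")
        if self.fs <= 2 * 45.0:
            raise InvalidArgumentError("fs must exceed 90 Hz (2 x 45 Hz)")
        if self.duration <= 0:
            raise InvalidArgumentError("duration must be positive")
        if self.beta_lo < 0 or self.beta_hi < 0 or self.beta_hi_sd < 0:
            raise InvalidArgumentError("exponents and their SD must be >= 0")
        if not 4.0 <= self.knee_freq <= 20.0:
            raise InvalidArgumentError("knee_freq must lie in [4, 20] Hz")
        if self.peak_height < 0:
            raise InvalidArgumentError("peak_height must be >= 0")
        if self.channel_labels is not None and len(self.channel_labels) != self.n_channels:
            raise InvalidArgumentError("channel_labels length != n_channels")

    def labels(self) -> list[str]:
        if self.channel_labels is not None:
            return [c.upper() for c in self.channel_labels]
        if self.n_channels > len(RETAINED_55):
            raise InvalidArgumentError(
                f"packaged montage has only {len(RETAINED_55)} channels"
            )
        return list(RETAINED_55[: self.n_channels])


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a two-group synthetic cohort.

    sigma_hi_mean_a/b and sigma_hi_between_subject_sd are targets for the
    *measured* DA-network sigma(beta_hi) (the scale group
    statistics are reported on). clinical_correlation is the target rank
    correlation between sigma(beta_hi) and the simulated positive-symptom
    score in group b. Defaults state the emulated cohort: 31 vs 30 subjects, group
    means 0.1264 / 0.0955, pooled between-subject SD 0.044 (recovered from
    the reference statistic t(59) = 2.7353 via d = t * sqrt(1/n1 + 1/n2)).
    """

    n_group_a: int = 31
    n_group_b: int = 30
    sigma_hi_mean_a: float = 0.1264
    sigma_hi_mean_b: float = 0.0955
    sigma_hi_between_subject_sd: float = 0.044
    mu_hi_mean: float = 2.0
    clinical_correlation: float = -0.4
    seed: int = 0
    group_labels: tuple[str, str] = ("HC", "SZ")
    # recording-level settings shared by all subjects
    n_channels: int = 55
    channel_labels: tuple[str, ...] | None = None
    fs: float = 256.0
    duration: float = 30.0
    beta_lo: float = 1.0
    knee_freq: float = 10.0
    peak_freq: float = 10.0
    peak_bandwidth: float = 1.0
    peak_height: float = 2.0

    def __post_init__(self) -> None:
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise InvalidArgumentError("group sizes must be >= 2")
        if abs(self.clinical_correlation) > 1:
            raise InvalidArgumentError("|clinical_correlation| must be <= 1")
        if min(self.sigma_hi_mean_a, self.sigma_hi_mean_b) <= 0:
            raise InvalidArgumentError("sigma targets must be positive")
        if self.sigma_hi_between_subject_sd < 0:
            raise InvalidArgumentError("between-subject SD must be >= 0")


# --- spectral synthesis primitives ----------------------------------------

def bimodal_psd(
    freqs: np.ndarray, beta_lo: float, beta_hi: float, knee_freq: float
) -> np.ndarray:
    """Piecewise power-law target spectrum, continuous at the knee.

    S(f) = f**-beta_lo for f <= knee, knee**(beta_hi-beta_lo) * f**-beta_hi
    above; S(0) is set to 0.
    """
    f = np.asarray(freqs, dtype=float)
    out = np.zeros_like(f)
    pos = f > 0
    lo = pos & (f <= knee_freq)
    hi = f > knee_freq
    out[lo] = f[lo] ** (-beta_lo)
    out[hi] = knee_freq ** (beta_hi - beta_lo) * f[hi] ** (-beta_hi)
    return out


def _synthesize(
    target_psd: np.ndarray, n: int, rng: np.random.Generator, n_rows: int = 1
) -> np.ndarray:
    """Inverse-FFT synthesis: amplitude sqrt(target_psd), uniform phases.

    Returns (n_rows, n); each row has independent phases. DC is zero, so
    rows are zero-mean by construction.
    """
    amp = np.sqrt(target_psd)
    ph = rng.uniform(0.0, 2.0 * np.pi, size=(n_rows, amp.size))
    spec = amp * np.exp(1j * ph)
    spec[:, 0] = 0.0
    if n % 2 == 0:
        spec[:, -1] = spec[:, -1].real  # Nyquist bin must be real
    return np.fft.irfft(spec, n=n, axis=-1)


def _rms_scale(target_psd: np.ndarray, n: int, rms: float) -> float:
    """Amplitude factor giving the synthesized rows an expected RMS."""
    var = (2.0 * target_psd[1:-1].sum() + target_psd[-1]) / n**2
    return rms / math.sqrt(var) if var > 0 else 1.0


def gen_powerlaw_noise(
    beta: float, n: int, fs: float, seed: int
) -> np.ndarray:
    """Single-channel 1/f**beta noise of length n, unit RMS."""
    if n < 2:
        raise InvalidArgumentError("n must be >= 2")
    if fs <= 0:
        raise InvalidArgumentError("fs must be positive")
    if beta < 0:
        raise InvalidArgumentError("beta must be >= 0")
    rng = np.random.default_rng(seed)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    psd = np.zeros_like(f)
    psd[1:] = f[1:] ** (-beta)
    x = _synthesize(psd, n, rng)[0]
    return x * _rms_scale(psd, n, 1.0)


def gen_bimodal_fractal(spec: SynthSpec, n: int) -> np.ndarray:
    """Single-channel signal with the spec's bimodal power-law spectrum."""
    if n < 2:
        raise InvalidArgumentError("n must be >= 2")
    rng = np.random.default_rng(spec.seed)
    f = np.fft.rfftfreq(n, d=1.0 / spec.fs)
    psd = bimodal_psd(f, spec.beta_lo, spec.beta_hi, spec.knee_freq)
    x = _synthesize(psd, n, rng)[0]
    return x * _rms_scale(psd, n, spec.rms_uv)


def add_oscillatory_peak(
    signal: np.ndarray,
    fs: float,
    peak_freq: float,
    peak_bandwidth: float,
    peak_height: float,
    seed: int,
) -> np.ndarray:
    """Add a narrowband stochastic oscillation to a signal.

    The added component has a Gaussian power bump centered at peak_freq
    (FWHM = peak_bandwidth) whose height is ``peak_height`` times the
    signal's spectral floor at peak_freq, the floor being estimated as the
    median raw-FFT power within +-2 FWHM of the peak. peak_height = 0
    returns the input unchanged.
    """
    signal = np.asarray(signal, dtype=float)
    if not 0 < peak_freq < fs / 2:
        raise InvalidArgumentError("peak_freq must lie in (0, fs/2)")
    if peak_height < 0:
        raise InvalidArgumentError("peak_height must be >= 0")
    if peak_bandwidth <= 0:
        raise InvalidArgumentError("peak_bandwidth must be positive")
    if peak_height == 0:
        return signal.copy()
    n = signal.shape[-1]
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    power = np.abs(np.fft.rfft(signal)) ** 2
    near = (np.abs(f - peak_freq) <= 2 * peak_bandwidth) & (f > 0)
    if near.sum() < 3:
        raise InvalidArgumentError("signal too short to estimate spectral floor")
    floor = float(np.median(power[near]))
    sigma_f = peak_bandwidth / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    bump = peak_height * floor * np.exp(-0.5 * ((f - peak_freq) / sigma_f) ** 2)
    rng = np.random.default_rng(seed)
    return signal + _synthesize(bump, n, rng)[0]


# --- dynamic recordings ----------------------------------------------------

def _segment_psd(
    spec: SynthSpec, beta_hi: float, n: int
) -> np.ndarray:
    """Fractal + oscillatory target spectrum for one segment."""
    f = np.fft.rfftfreq(n, d=1.0 / spec.fs)
    psd = bimodal_psd(f, spec.beta_lo, beta_hi, spec.knee_freq)
    if spec.peak_height > 0:
        floor = bimodal_psd(
            np.array([spec.peak_freq]), spec.beta_lo, beta_hi, spec.knee_freq
        )[0]
        sigma_f = spec.peak_bandwidth / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        psd = psd + spec.peak_height * floor * np.exp(
            -0.5 * ((f - spec.peak_freq) / sigma_f) ** 2
        )
    return psd


def gen_dynamic_recording(spec: SynthSpec) -> Recording:
    """Multichannel recording with segment-wise high-band exponent dynamics.

    One segment per sliding-window step (window_seconds * (1 -
    window_overlap), i.e. 2 s at defaults); each segment's high-band
    exponent is drawn from Normal(beta_hi, beta_hi_sd) truncated at 0,
    shared across channels. Consecutive segments are joined with
    equal-power cosine cross-fades of half a step. With beta_hi_sd = 0 the
    whole duration is synthesized as a single stationary segment.

    The drawn exponent sequence is stored in ``meta['beta_hi_draws']``.
    """
    if spec.duration < spec.window_seconds:
        raise InvalidArgumentError(
            f"duration {spec.duration} s shorter than one analysis window "
            f"({spec.window_seconds} s)"
        )
    rng = np.random.default_rng(spec.seed)
    n_total = int(round(spec.duration * spec.fs))
    labels = spec.labels()
    scale_ref = None

    if spec.beta_hi_sd == 0:
        psd = _segment_psd(spec, spec.beta_hi, n_total)
        data = _synthesize(psd, n_total, rng, n_rows=spec.n_channels)
        data *= _rms_scale(psd, n_total, spec.rms_uv)
        draws = np.full(1, spec.beta_hi)
    else:
        step = spec.window_seconds * (1.0 - spec.window_overlap)
        seg_len = int(round(step * spec.fs))
        fade = seg_len // 2
        n_seg = int(np.ceil(n_total / seg_len))
        draws = np.clip(
            rng.normal(spec.beta_hi, spec.beta_hi_sd, size=n_seg), 0.0, None
        )
        data = np.zeros((spec.n_channels, n_total))
        t = np.arange(fade)
        ramp_up = np.sin(0.5 * np.pi * (t + 0.5) / fade)
        ramp_dn = np.cos(0.5 * np.pi * (t + 0.5) / fade)
        for s in range(n_seg):
            start = s * seg_len
            ext = min(seg_len + fade, n_total - start)
            if ext <= 0:
                break
            psd = _segment_psd(spec, draws[s], ext)
            seg = _synthesize(psd, ext, rng, n_rows=spec.n_channels)
            if scale_ref is None:
                # one common amplitude scale so segment-to-segment power
                # differences reflect the exponent draws only
                ref_psd = _segment_psd(spec, spec.beta_hi, ext)
                scale_ref = _rms_scale(ref_psd, ext, spec.rms_uv)
            seg *= scale_ref
            if s > 0:
                seg[:, :fade] *= ramp_up[: min(fade, ext)]
            if ext == seg_len + fade:
                seg[:, seg_len:] *= ramp_dn
            data[:, start : start + ext] += seg
    return Recording(
        data=data,
        fs=spec.fs,
        channel_labels=labels,
        subject_id=f"synth-{spec.seed}",
        group="synthetic",
        meta={"beta_hi_draws": draws, "spec": spec},
    )


# --- cohorts ---------------------------------------------------------------

def sigma_target_to_beta_hi_sd(target: float) -> float:
    """Invert the measured-sigma calibration table: generative SD that
    yields a measured DA-level sigma(beta_hi) of ``target`` in expectation.

    Targets at or below the estimation-noise floor map to 0; targets beyond
    the table are extrapolated with the final slope.
    """
    s, m = np.asarray(_SIGMA_CAL_S), np.asarray(_SIGMA_CAL_MEAN)
    if target <= m[0]:
        return 0.0
    if target >= m[-1]:
        return float(s[-1] + (target - m[-1]) * (s[-1] - s[-2]) / (m[-1] - m[-2]))
    return float(np.interp(target, m, s))


def expected_measured_sigma(beta_hi_sd: float) -> float:
    """Forward calibration model: expected measured DA-level sigma."""
    s, m = np.asarray(_SIGMA_CAL_S), np.asarray(_SIGMA_CAL_MEAN)
    if beta_hi_sd >= s[-1]:
        return float(m[-1] + (beta_hi_sd - s[-1]) * (m[-1] - m[-2]) / (s[-1] - s[-2]))
    return float(np.interp(beta_hi_sd, s, m))


def _trunc_normal(rng, mean, sd, size, lower=0.0):
    """Normal draws resampled until strictly above ``lower``."""
    out = rng.normal(mean, sd, size=size)
    for _ in range(1000):
        bad = out <= lower
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    raise RuntimeError("truncated-normal resampling did not converge")


def gen_cohort(cspec: CohortSpec) -> tuple[list[Recording], "pandas.DataFrame"]:
    """Generate a two-group cohort: recordings plus a cohort table.

    Per subject, a measured-scale sigma(beta_hi) target is drawn from
    Normal(group mean, between-subject SD deconvolved of estimation noise),
    truncated at 0, and mapped to a generative beta_hi_sd through the
    packaged calibration. Group b additionally receives a simulated
    positive-symptom (PANSS POS) score constructed via a Gaussian copula to
    have the requested rank correlation with the subject's sigma target.
    Demographics are decorative draws matched to published cohort
    summary distributions. The generator-truth columns ``latent_sigma_target`` and
    ``latent_beta_hi_sd`` are included for testing.
    """
    import pandas as pd

    ss = np.random.SeedSequence(cspec.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    n_a, n_b = cspec.n_group_a, cspec.n_group_b
    n = n_a + n_b
    latent_sd = math.sqrt(
        max(cspec.sigma_hi_between_subject_sd**2 - _SIGMA_MEAS_SD**2, 1e-8)
    )
    targets = np.concatenate(
        [
            _trunc_normal(rng, cspec.sigma_hi_mean_a, latent_sd, n_a),
            _trunc_normal(rng, cspec.sigma_hi_mean_b, latent_sd, n_b),
        ]
    )
    beta_hi_sds = np.array([sigma_target_to_beta_hi_sd(t) for t in targets])
    groups = [cspec.group_labels[0]] * n_a + [cspec.group_labels[1]] * n_b

    recordings = []
    for i, child in enumerate(ss.spawn(n + 1)[:n]):
        seed_i = int(child.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
        sspec = SynthSpec(
            n_channels=cspec.n_channels,
            channel_labels=cspec.channel_labels,
            fs=cspec.fs,
            duration=cspec.duration,
            beta_lo=cspec.beta_lo,
            beta_hi=cspec.mu_hi_mean,
            knee_freq=cspec.knee_freq,
            peak_freq=cspec.peak_freq,
            peak_bandwidth=cspec.peak_bandwidth,
            peak_height=cspec.peak_height,
            beta_hi_sd=float(beta_hi_sds[i]),
            seed=seed_i,
        )
        rec = gen_dynamic_recording(sspec)
        rec.subject_id = f"S{i:03d}"
        rec.group = groups[i]
        recordings.append(rec)

    # simulated PANSS positive score for group b: Gaussian copula with the
    # requested rank correlation against the sigma target
    rho = cspec.clinical_correlation
    rho_g = 2.0 * math.sin(math.pi * rho / 6.0)  # Pearson giving Spearman rho
    tb = targets[n_a:]
    zx = (tb - tb.mean()) / tb.std() if tb.std() > 0 else np.zeros(n_b)
    z = rho_g * zx + math.sqrt(max(1.0 - rho_g**2, 0.0)) * rng.standard_normal(n_b)
    panss_pos_b = np.clip(np.round(14.63 + 5.12 * z), 7, 49)

    age = np.clip(np.round(rng.normal(33.0, 10.0, n)), 18, 65)
    sex = rng.choice(["F", "M"], size=n, p=[0.4, 0.6])
    edu = np.clip(np.round(rng.normal(15.5, 2.5, n)), 8, 22)
    illness = np.clip(rng.normal(8.17, 8.57, n_b), 0.5, 40.0).round(1)
    cpz = np.clip(rng.normal(394.16, 346.01, n_b), 25.0, 1500.0).round(0)
    panss_neg_b = np.clip(np.round(rng.normal(15.90, 5.70, n_b)), 7, 49)
    panss_gen_b = np.clip(np.round(rng.normal(30.10, 9.05, n_b)), 16, 112)

    nanpad = [np.nan] * n_a
    table = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in recordings],
            "group": groups,
            "age": age,
            "sex": sex,
            "education_years": edu,
            "illness_duration": nanpad + list(illness),
            "cpz": nanpad + list(cpz),
            "panss_pos": nanpad + list(panss_pos_b),
            "panss_neg": nanpad + list(panss_neg_b),
            "panss_gen": nanpad + list(panss_gen_b),
            "panss_sum": nanpad
            + list(panss_pos_b + panss_neg_b + panss_gen_b),
            "latent_sigma_target": targets,
            "latent_beta_hi_sd": beta_hi_sds,
        }
    )
    return recordings, table
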