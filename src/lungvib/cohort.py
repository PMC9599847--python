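"""Synthetic cohorts of chest-wall vibration recordings.

No public recordings of the contact-free vibration device exist, so the
whole analysis chain is exercised on simulated cohorts that reproduce the
structure of the real data: subjects with case/control labels and
clinically shifted covariates, several measurements per subject, and
single-channel vibration signals containing

* a quasi-periodic train of S1/S2 heart-sound wavelets (Gabor-like damped
  sinusoids, ≈40 ms support) whose amplitude is modulated by respiration,
* an asymmetric low-frequency respiration wave (rising inhale segment,
  longer falling exhale),
* a lung-congestion signature for cases only — band-limited noise energy
  plus sparse 10–20 ms crackle transients confined to the inhale phase,
* nuisance components tied to comorbidities, not to the label: a systolic
  murmur band (valvular disorder) and a narrowband exhale wheeze
  (respiratory condition), both placed above the feature band grid,
* white measurement noise.

How congestion manifests in the measured vibration signal is not public;
the inhale-phase band-energy/crackle model used here is an explicit
modeling assumption, configurable via ``SignalModelConfig``.

Every measurement draws from its own RNG stream derived from
(seed, subject_id, measurement_id), so cohorts are bit-reproducible and
individual measurements can be regenerated in isolation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps

from .landmarks import LandmarkSet, butterworth_filter

__all__ = [
    "SubjectRecord",
    "SignalModelConfig",
    "CovariateConfig",
    "VibrationMeasurement",
    "generate_cohort",
    "synthesize_heartbeat_train",
    "synthesize_respiration_wave",
    "synthesize_measurement",
    "generate_measurements",
]


@dataclass
class SubjectRecord:
    subject_id: str
    congested: bool
    age: float  # years
    sex: str  # "M" / "F"
    bmi: float  # kg/m^2
    heart_failure_history: bool
    respiratory_condition: bool
    valvular_disorder: bool
    n_measurements: int = 1


@dataclass
class CovariateConfig:
    """Case/control covariate distributions.

    The default draws every covariate from the same clinic-like marginal
    distribution for cases and controls, so with the congestion effect
    switched off the case and control signal distributions are identical
    and null-behaviour checks are exact.  ``clinic_shifted()`` gives a
    heart-failure-cohort-like imbalance (cases older, heavier, more
    valvular/respiratory comorbidity) for studying confounded cohorts —
    note that comorbidity then carries acoustic label information
    (murmur, wheeze) even without congestion.
    """

    age_control: tuple[float, float] = (68.0, 14.0)  # mean, sd years
    age_case: tuple[float, float] = (68.0, 14.0)
    bmi_control: tuple[float, float] = (28.0, 6.0)
    bmi_case: tuple[float, float] = (28.0, 6.0)
    male_frac_control: float = 0.65
    male_frac_case: float = 0.65
    hf_history_control: float = 0.68
    hf_history_case: float = 0.68
    respiratory_control: float = 0.15
    respiratory_case: float = 0.15
    valvular_control: float = 0.40
    valvular_case: float = 0.40

    @classmethod
    def clinic_shifted(cls) -> "CovariateConfig":
        """Case/control imbalance resembling a real HF follow-up cohort."""
        return cls(
            age_control=(65.0, 15.0),
            age_case=(73.0, 12.0),
            bmi_control=(28.0, 5.0),
            bmi_case=(29.0, 6.0),
            male_frac_control=0.60,
            male_frac_case=0.71,
            hf_history_control=0.60,
            hf_history_case=0.77,
            respiratory_control=0.09,
            respiratory_case=0.22,
            valvular_control=0.23,
            valvular_case=0.61,
        )


@dataclass
class SignalModelConfig:
    """Parameters of the vibration-signal generative model.

    Amplitudes are in arbitrary device units with the S1 wavelet amplitude
    as the reference scale (s1_amp = 1).  ``congestion_effect`` is a
    dimensionless effect size: the congestion band-noise RMS during
    inhalation equals ``congestion_effect × congestion_base_amp``.
    """

    fs: float = 500.0  # Hz; heart-sound wavelets ≤ 100 Hz with margin
    duration: float = 120.0  # s, the 2-min spot measurement
    heart_rate_mean: float = 70.0  # bpm
    heart_rate_sd: float = 3.0  # bpm (beat-to-beat jitter)
    systole_fraction: float = 0.35  # S1→S2 gap as a fraction of RR
    s1_center_freq: float = 25.0  # Hz
    s2_center_freq: float = 45.0  # Hz
    s1_amp: float = 1.0
    s2_amp: float = 0.6
    wavelet_sigma_ms: float = 8.0  # Gabor envelope sd; ≈40 ms support
    resp_rate: float = 15.0  # breaths/min
    inhale_fraction: float = 0.4  # inhale share of the cycle
    resp_mod_depth: float = 0.25  # heart-sound amplitude modulation
    baseline_gain: float = 0.5  # respiration wave leaking into the channel
    congestion_effect: float = 0.0  # effect size d >= 0
    congestion_band: tuple[float, float] = (2.0, 4.0)  # Hz
    congestion_base_amp: float = 0.05  # RMS per unit effect
    crackle_rate: float = 2.0  # expected crackles per inhale (cases)
    murmur_amp: float = 0.1  # systolic band-noise RMS (valvular disorder)
    wheeze_amp: float = 0.1  # exhale tone amplitude (respiratory condition)
    noise_sd: float = 0.05  # white measurement noise
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.systole_fraction < 0.5):
            raise ValueError("systole_fraction must be in (0, 0.5)")
        if not (0 < self.inhale_fraction < 1):
            raise ValueError("inhale_fraction must be in (0, 1)")
        if self.fs <= 4 * max(self.s1_center_freq, self.s2_center_freq):
            raise ValueError("fs must exceed 4x the highest heart-sound center frequency")
        if self.congestion_effect < 0:
            raise ValueError("congestion_effect must be >= 0")
        if self.resp_rate <= 0 or self.heart_rate_mean <= 0 or self.duration <= 0:
            raise ValueError("rates and duration must be positive")
        lo, hi = self.congestion_band
        if not (0 < lo < hi < self.fs / 2):
            raise ValueError("congestion_band must be increasing and below Nyquist")


@dataclass
class VibrationMeasurement:
    """A single-channel chest-vibration recording with subject linkage."""

    subject_id: str
    measurement_id: str
    fs: float
    samples: np.ndarray
    truth_landmarks: LandmarkSet | None = None

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def cropped(self, duration_s: float) -> "VibrationMeasurement":
        """First ``duration_s`` seconds, with truth landmarks restricted."""
        n = int(round(duration_s * self.fs))
        if n > len(self.samples):
            raise ValueError("crop longer than measurement")
        truth = self.truth_landmarks.restricted(0.0, duration_s) if self.truth_landmarks else None
        return VibrationMeasurement(
            subject_id=self.subject_id,
            measurement_id=self.measurement_id,
            fs=self.fs,
            samples=self.samples[:n],
            truth_landmarks=truth,
        )


def _stream(seed: int, *tokens: str) -> np.random.Generator:
    # stable (non-salted) per-item RNG stream
    h = hashlib.sha256("/".join(tokens).encode()).digest()
    words = [int.from_bytes(h[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *words]))


def generate_cohort(
    n_subjects: int,
    case_fraction: float,
    measurements_per_subject: int = 1,
    covariate_config: CovariateConfig | None = None,
    seed: int = 0,
) -> list[SubjectRecord]:
    """Draw a labeled cohort with case/control-shifted covariates.

    Exactly ``round(n_subjects × case_fraction)`` subjects are congested.
    Deterministic given ``seed``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if not (0 <= case_fraction <= 1):
        raise ValueError("case_fraction must be in [0, 1]")
    if measurements_per_subject < 1:
        raise ValueError("measurements_per_subject must be >= 1")
    n_cases = int(round(n_subjects * case_fraction))
    if 0 < case_fraction < 1 and (n_cases == 0 or n_cases == n_subjects):
        raise ValueError("requested both classes but rounding left one empty")
    cov = covariate_config or CovariateConfig()
    width = max(3, len(str(n_subjects)))
    subjects = []
    for i in range(n_subjects):
        congested = i < n_cases
        sid = f"S{i:0{width}d}"
        rng = _stream(seed, "subject", sid)
        age_mu, age_sd = cov.age_case if congested else cov.age_control
        bmi_mu, bmi_sd = cov.bmi_case if congested else cov.bmi_control
        male_p = cov.male_frac_case if congested else cov.male_frac_control
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                congested=congested,
                age=float(np.clip(rng.normal(age_mu, age_sd), 18, 100)),
                sex="M" if rng.random() < male_p else "F",
                bmi=float(np.clip(rng.normal(bmi_mu, bmi_sd), 15, 55)),
                heart_failure_history=bool(
                    rng.random() < (cov.hf_history_case if congested else cov.hf_history_control)
                ),
                respiratory_condition=bool(
                    rng.random() < (cov.respiratory_case if congested else cov.respiratory_control)
                ),
                valvular_disorder=bool(
                    rng.random() < (cov.valvular_case if congested else cov.valvular_control)
                ),
                n_measurements=measurements_per_subject,
            )
        )
    return subjects


def _gabor(t: np.ndarray, center: float, freq: float, amp: float, sigma: float) -> np.ndarray:
    tt = t - center
    return amp * np.exp(-(tt**2) / (2 * sigma**2)) * np.sin(2 * np.pi * freq * tt)


def synthesize_heartbeat_train(
    cfg: SignalModelConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Place S1/S2 Gabor wavelets on a jittered beat grid.

    Beat onsets advance by RR = 60/heart_rate_mean with Gaussian jitter of
    sd equivalent to ``heart_rate_sd`` (RR sd = RR·hr_sd/hr_mean); S2
    follows S1 by ``systole_fraction`` of that beat's RR.  Returns
    (signal, s1_times, s2_times), both time arrays strictly increasing and
    alternating S1 < S2 < next S1.
    """
    cfg.validate()
    n = int(round(cfg.fs * cfg.duration))
    t = np.arange(n) / cfg.fs
    x = np.zeros(n)
    rr_nom = 60.0 / cfg.heart_rate_mean
    rr_sd = rr_nom * cfg.heart_rate_sd / cfg.heart_rate_mean
    sigma = cfg.wavelet_sigma_ms / 1000.0
    s1_times, s2_times = [], []
    tk = 0.25  # first beat shortly after start
    while tk < cfg.duration:
        rr = rr_nom if rr_sd == 0 else float(np.clip(rng.normal(rr_nom, rr_sd), 0.3, 2.0))
        t2 = tk + cfg.systole_fraction * rr
        s1_times.append(tk)
        if t2 < cfg.duration:
            s2_times.append(t2)
        # add wavelets over a +-4 sigma support window only
        for center, f0, amp in ((tk, cfg.s1_center_freq, cfg.s1_amp), (t2, cfg.s2_center_freq, cfg.s2_amp)):
            i0 = max(0, int((center - 4 * sigma) * cfg.fs))
            i1 = min(n, int((center + 4 * sigma) * cfg.fs) + 1)
            if i1 > i0:
                x[i0:i1] += _gabor(t[i0:i1], center, f0, amp, sigma)
        tk += rr
    return x, np.asarray(s1_times), np.asarray(s2_times)


def synthesize_respiration_wave(
    cfg: SignalModelConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, list[tuple[float, float]], list[tuple[float, float]]]:
    """Asymmetric piecewise-sinusoidal respiration wave in [-1, 1].

    Each cycle of period 60/resp_rate rises from -1 to +1 over the inhale
    segment (``inhale_fraction`` of the cycle) and falls back over the
    exhale segment.  Returns the wave and the full inhale/exhale intervals
    contained in the recording.
    """
    if cfg.resp_rate <= 0:
        raise ValueError("resp_rate must be positive")
    n = int(round(cfg.fs * cfg.duration))
    t = np.arange(n) / cfg.fs
    period = 60.0 / cfg.resp_rate
    fi = cfg.inhale_fraction
    phase = (t % period) / period
    wave = np.where(
        phase < fi,
        -np.cos(np.pi * phase / fi),
        np.cos(np.pi * (phase - fi) / (1 - fi)),
    )
    inhale, exhale = [], []
    k = 0
    while True:
        start = k * period
        mid = start + fi * period
        end = (k + 1) * period
        if mid <= cfg.duration + 1e-9:
            inhale.append((start, min(mid, cfg.duration)))
        if start >= cfg.duration - 1e-9:
            break
        if end <= cfg.duration + 1e-9:
            exhale.append((mid, end))
        else:
            break
        k += 1
    inhale = [iv for iv in inhale if iv[1] - iv[0] > 1e-9 and iv[1] <= cfg.duration + 1e-9]
    return wave, inhale, exhale


def _interval_mask(n: int, fs: float, intervals: Sequence[tuple[float, float]], smooth_s: float = 0.2) -> np.ndarray:
    mask = np.zeros(n)
    for a, b in intervals:
        mask[int(round(a * fs)) : int(round(b * fs))] = 1.0
    win = max(1, int(round(smooth_s * fs)))
    kernel = np.hanning(win + 2)[1:-1]
    kernel /= kernel.sum()
    return np.convolve(mask, kernel, mode="same")


def _band_noise(rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    lo = max(band[0], 1e-3)
    hi = min(band[1], 0.45 * fs)
    x = butterworth_filter(rng.standard_normal(n), fs, (lo, hi), "bandpass")
    rms = float(np.sqrt(np.mean(x**2)))
    return x / rms if rms > 0 else x


def synthesize_measurement(subject: SubjectRecord, cfg: SignalModelConfig, measurement_id: str | None = None) -> VibrationMeasurement:
    """Generate one labeled vibration recording for a subject.

    samples = heart_train · (1 + resp_mod_depth · wave)
              + baseline_gain · wave
              + congestion (cases only; inhale-confined band noise + crackles)
              + murmur (valvular disorder; systolic 100–200 Hz band noise)
              + wheeze (respiratory condition; exhale narrowband tone)
              + white noise.
    """
    cfg.validate()
    mid = measurement_id or f"{subject.subject_id}-m00"
    rng = _stream(cfg.seed, "measurement", subject.subject_id, mid)
    n = int(round(cfg.fs * cfg.duration))

    heart, s1_times, s2_times = synthesize_heartbeat_train(cfg, rng)
    wave, inhale, exhale = synthesize_respiration_wave(cfg)
    x = heart * (1 + cfg.resp_mod_depth * wave) + cfg.baseline_gain * wave

    if subject.congested and cfg.congestion_effect > 0:
        amp = cfg.congestion_effect * cfg.congestion_base_amp
        mask = _interval_mask(n, cfg.fs, inhale)
        x += amp * _band_noise(rng, n, cfg.fs, cfg.congestion_band) * mask
        # sparse short crackle transients during inhalation
        t = np.arange(n) / cfg.fs
        for a, b in inhale:
            for _ in range(rng.poisson(cfg.crackle_rate)):
                tc = rng.uniform(a, min(b, cfg.duration - 0.05))
                dur = rng.uniform(0.010, 0.020)
                i0, i1 = int(tc * cfg.fs), min(n, int((tc + dur) * cfg.fs))
                tt = t[i0:i1] - tc
                x[i0:i1] += 1.5 * amp * np.exp(-tt / (dur / 3)) * np.sin(2 * np.pi * 50.0 * tt)

    if subject.valvular_disorder and cfg.murmur_amp > 0:
        # systolic band noise, placed above the analysis band grid
        murmur_iv = [(a + 0.03, b) for a, b in zip(s1_times, s2_times) if b - a > 0.05]
        if murmur_iv:
            mask = _interval_mask(n, cfg.fs, murmur_iv, smooth_s=0.03)
            x += cfg.murmur_amp * _band_noise(rng, n, cfg.fs, (100.0, 200.0)) * mask

    if subject.respiratory_condition and cfg.wheeze_amp > 0:
        f_wheeze = min(150.0, 0.4 * cfg.fs)
        t = np.arange(n) / cfg.fs
        mask = _interval_mask(n, cfg.fs, exhale)
        x += cfg.wheeze_amp * np.sin(2 * np.pi * f_wheeze * t + rng.uniform(0, 2 * np.pi)) * mask

    if cfg.noise_sd > 0:
        x += rng.normal(0.0, cfg.noise_sd, n)

    truth = LandmarkSet(
        s1_times=s1_times,
        s2_times=s2_times,
        inhale_intervals=inhale,
        exhale_intervals=exhale,
    )
    return VibrationMeasurement(
        subject_id=subject.subject_id,
        measurement_id=mid,
        fs=cfg.fs,
        samples=x,
        truth_landmarks=truth,
    )


def generate_measurements(
    subjects: Iterable[SubjectRecord], cfg: SignalModelConfig
) -> list[VibrationMeasurement]:
    """All measurements for a cohort (n_measurements per subject)."""
    out = []
    for s in subjects:
        for j in range(s.n_measurements):
            out.append(synthesize_measurement(s, cfg, measurement_id=f"{s.subject_id}-m{j:02d}"))
    return out
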