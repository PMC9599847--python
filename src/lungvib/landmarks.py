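"""Signal conditioning and physiological landmark detection.

The front half of the analysis pipeline: a raw chest-wall vibration
recording is split into overlapping buffers; within each buffer the first
and second heart sounds (S1, S2 — the valve-closure transients) are
located as peaks of the envelope of the high-passed signal, and the
inhale/exhale phases are delimited from the low-passed respiration wave.
A short-time Fourier spectrogram of the buffer supports the
frequency-domain features downstream.

All landmark times are expressed on the measurement clock (seconds from
the start of the recording), so buffers cut from the same measurement can
be compared against a single ground-truth landmark set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "SignalBuffer",
    "LandmarkSet",
    "Spectrogram",
    "split_buffers",
    "butterworth_filter",
    "signal_envelope",
    "detect_heart_sounds",
    "delimit_respiratory_phases",
    "detect_landmarks",
    "compute_spectrogram",
]


@dataclass
class SignalBuffer:
    """A windowed excerpt of one measurement."""

    measurement_id: str
    start_time: float  # s, on the measurement clock
    fs: float  # Hz
    samples: np.ndarray

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


@dataclass
class LandmarkSet:
    """Heart-sound events and respiratory phase intervals for one buffer.

    ``s1_times``/``s2_times`` are strictly increasing and pairwise aligned:
    ``s2_times[i]`` falls between ``s1_times[i]`` and ``s1_times[i+1]``.
    Inhale and exhale intervals are disjoint ``(start, end)`` pairs that
    partition the buffer up to boundary partial cycles.
    """

    s1_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    s2_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    inhale_intervals: list[tuple[float, float]] = field(default_factory=list)
    exhale_intervals: list[tuple[float, float]] = field(default_factory=list)

    @property
    def has_heart(self) -> bool:
        return len(self.s1_times) >= 2 and len(self.s2_times) >= 2

    @property
    def has_respiration(self) -> bool:
        return len(self.inhale_intervals) >= 1 and len(self.exhale_intervals) >= 1

    @property
    def quality_ok(self) -> bool:
        return self.has_heart and self.has_respiration

    def restricted(self, start: float, end: float) -> "LandmarkSet":
        """Landmarks clipped to the window [start, end)."""
        s1 = np.asarray(self.s1_times, dtype=float)
        s2 = np.asarray(self.s2_times, dtype=float)
        return LandmarkSet(
            s1_times=s1[(s1 >= start) & (s1 < end)],
            s2_times=s2[(s2 >= start) & (s2 < end)],
            inhale_intervals=[iv for iv in self.inhale_intervals if iv[0] >= start and iv[1] <= end],
            exhale_intervals=[iv for iv in self.exhale_intervals if iv[0] >= start and iv[1] <= end],
        )

    def to_dict(self) -> dict:
        return {
            "s1_times": np.asarray(self.s1_times, dtype=float).tolist(),
            "s2_times": np.asarray(self.s2_times, dtype=float).tolist(),
            "inhale_intervals": [list(iv) for iv in self.inhale_intervals],
            "exhale_intervals": [list(iv) for iv in self.exhale_intervals],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        return cls(
            s1_times=np.asarray(d["s1_times"], dtype=float),
            s2_times=np.asarray(d["s2_times"], dtype=float),
            inhale_intervals=[tuple(iv) for iv in d["inhale_intervals"]],
            exhale_intervals=[tuple(iv) for iv in d["exhale_intervals"]],
        )


@dataclass
class Spectrogram:
    """One-sided short-time Fourier power of a buffer.

    ``times`` are frame centers on the measurement clock; ``power`` has
    shape (len(freqs), len(times)) and is a power spectral density
    (units² / Hz), non-negative everywhere.
    """

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray


def split_buffers(measurement, buffer_s: float = 60.0, step_s: float = 30.0) -> list[SignalBuffer]:
    """Cut a measurement into overlapping fixed-length buffers.

    Buffers start at 0, step_s, 2·step_s, …; only full-length windows are
    produced, so the count is ``floor((duration − buffer_s)/step_s) + 1``.
    """
    if step_s <= 0:
        raise ValueError("step_s must be positive")
    fs = measurement.fs
    duration = len(measurement.samples) / fs
    if buffer_s > duration + 1e-9:
        raise ValueError(
            f"buffer_s={buffer_s} exceeds measurement duration {duration:.3f} s"
        )
    n = int(np.floor((duration - buffer_s) / step_s + 1e-9)) + 1
    nbuf = int(round(buffer_s * fs))
    buffers = []
    for i in range(n):
        start = i * step_s
        i0 = int(round(start * fs))
        buffers.append(
            SignalBuffer(
                measurement_id=measurement.measurement_id,
                start_time=start,
                fs=fs,
                samples=np.asarray(measurement.samples[i0 : i0 + nbuf], dtype=float),
            )
        )
    return buffers


def butterworth_filter(
    x: np.ndarray,
    fs: float,
    cutoff,
    mode: str = "highpass",
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth filter (forward–backward application).

    ``cutoff`` is a scalar for highpass/lowpass or a (low, high) pair for
    bandpass; all cutoffs must lie strictly inside (0, fs/2).
    """
    nyq = fs / 2.0
    cut = np.atleast_1d(np.asarray(cutoff, dtype=float))
    if np.any(cut <= 0) or np.any(cut >= nyq):
        raise ValueError(f"cutoff {cutoff} outside (0, Nyquist={nyq})")
    if mode == "bandpass":
        if cut.size != 2 or cut[0] >= cut[1]:
            raise ValueError("bandpass needs an increasing (low, high) pair")
        wn = cut
    elif mode in ("highpass", "lowpass"):
        if cut.size != 1:
            raise ValueError(f"{mode} needs a scalar cutoff")
        wn = cut[0]
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    sos = sps.butter(order, wn, btype=mode, fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def signal_envelope(x: np.ndarray, fs: float, smooth_ms: float = 20.0) -> np.ndarray:
    """Magnitude of the analytic signal, smoothed by a short moving average."""
    x = np.asarray(x, dtype=float)
    win = max(1, int(round(fs * smooth_ms / 1000.0)))
    if len(x) < win:
        raise ValueError("signal shorter than smoothing window")
    env = np.abs(sps.hilbert(x))
    kernel = np.ones(win) / win
    return np.convolve(env, kernel, mode="same")


def _pair_s1_s2(peak_times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Alternating-interval rule: within a beat the S1→S2 gap (systole) is
    # shorter than the S2→next-S1 gap, so the parity whose outgoing gaps
    # are shorter on average opens the systolic interval and marks S1.
    gaps = np.diff(peak_times)
    even = np.mean(gaps[0::2]) if len(gaps[0::2]) else np.inf
    odd = np.mean(gaps[1::2]) if len(gaps[1::2]) else np.inf
    p = 0 if even <= odd else 1
    s1 = peak_times[p::2]
    s2 = peak_times[p + 1 :: 2]
    n = min(len(s1), len(s2))
    return s1[:n], s2[:n]


def detect_heart_sounds(
    b: SignalBuffer,
    hp_cutoff: float = 15.0,
    min_separation_ms: float = 200.0,
    smooth_ms: float = 20.0,
    threshold_factor: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Locate S1 and S2 heart sounds in one buffer.

    The buffer is high-passed to isolate the heart-sound band, its envelope
    is thresholded at ``threshold_factor`` × the median envelope (an
    adaptive floor that scales with the recording gain), and peaks at
    least ``min_separation_ms`` apart are paired into (S1, S2) by the
    alternating-interval rule.  Fewer than 4 peaks flags the buffer as
    low quality and returns empty arrays rather than raising.
    """
    hp = butterworth_filter(b.samples, b.fs, hp_cutoff, "highpass")
    env = signal_envelope(hp, b.fs, smooth_ms)
    med = float(np.median(env))
    if med <= 0:
        return np.empty(0), np.empty(0)
    distance = max(1, int(round(b.fs * min_separation_ms / 1000.0)))
    idx, _ = sps.find_peaks(env, height=threshold_factor * med, distance=distance)
    if len(idx) < 4:
        return np.empty(0), np.empty(0)
    times = b.start_time + idx / b.fs
    return _pair_s1_s2(times)


def delimit_respiratory_phases(
    b: SignalBuffer,
    lp_cutoff: float = 1.0,
    min_extremum_separation_s: float = 1.0,
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Delimit inhale and exhale intervals from the low-passed wave.

    Troughs→peaks of the respiration wave are inhale intervals and
    peaks→troughs exhale; extrema need 10% of the wave's range in
    prominence and at least ``min_extremum_separation_s`` separation.
    A flat buffer yields no extrema and is flagged (empty lists).
    """
    low = butterworth_filter(b.samples, b.fs, lp_cutoff, "lowpass")
    low = low - np.mean(low)
    rng = float(np.ptp(low))
    # flat recordings produce only numerical ripple after filtering
    if rng <= 1e-9 * max(1.0, float(np.max(np.abs(b.samples)))):
        return [], []
    distance = max(1, int(round(b.fs * min_extremum_separation_s)))
    prom = 0.1 * rng
    peaks, _ = sps.find_peaks(low, distance=distance, prominence=prom)
    troughs, _ = sps.find_peaks(-low, distance=distance, prominence=prom)
    if len(peaks) == 0 or len(troughs) == 0:
        return [], []
    # merge into an alternating extremum sequence, keeping the more extreme
    # of any two same-type neighbours
    ext = sorted([(i, +1) for i in peaks] + [(i, -1) for i in troughs])
    cleaned: list[tuple[int, int]] = []
    for i, kind in ext:
        if cleaned and cleaned[-1][1] == kind:
            prev = cleaned[-1][0]
            better = i if kind * low[i] > kind * low[prev] else prev
            cleaned[-1] = (better, kind)
        else:
            cleaned.append((i, kind))
    inhale, exhale = [], []
    for (i0, k0), (i1, k1) in zip(cleaned[:-1], cleaned[1:]):
        t0 = b.start_time + i0 / b.fs
        t1 = b.start_time + i1 / b.fs
        if k0 == -1 and k1 == +1:
            inhale.append((t0, t1))
        elif k0 == +1 and k1 == -1:
            exhale.append((t0, t1))
    return inhale, exhale


def detect_landmarks(b: SignalBuffer, config=None) -> LandmarkSet:
    """Full landmark pass over one buffer (heart sounds + respiration)."""
    kw = {}
    if config is not None:
        kw = dict(
            hp_cutoff=config.hp_cutoff,
            min_separation_ms=config.min_separation_ms,
            smooth_ms=config.smooth_ms,
        )
    s1, s2 = detect_heart_sounds(b, **kw)
    lp = config.lp_cutoff if config is not None else 1.0
    inhale, exhale = delimit_respiratory_phases(b, lp_cutoff=lp)
    return LandmarkSet(s1_times=s1, s2_times=s2, inhale_intervals=inhale, exhale_intervals=exhale)


def compute_spectrogram(
    b: SignalBuffer, window_s: float = 2.0, overlap_frac: float = 0.75
) -> Spectrogram:
    """One-sided Hann-window short-time power spectral density of a buffer."""
    nperseg = int(round(window_s * b.fs))
    if nperseg >= len(b.samples):
        raise ValueError("spectrogram window longer than buffer")
    noverlap = int(round(overlap_frac * nperseg))
    freqs, t, power = sps.spectrogram(
        np.asarray(b.samples, dtype=float),
        fs=b.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        scaling="density",
        mode="psd",
    )
    return Spectrogram(times=b.start_time + t, freqs=freqs, power=power)
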