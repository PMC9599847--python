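"""Landmark-driven time and frequency feature engineering.

Time features are distances and mean amplitudes between the heart-sound
and respiratory landmarks (beat intervals, envelope amplitudes at S1/S2,
breathing timing).  Frequency features section the buffer spectrogram
vertically into octave-spaced frequency bands and horizontally into the
inhale/exhale phases delimited by the landmarks; the mean spectral power
of each (band, phase) cross-section is a feature, plus an inhale/exhale
energy ratio per band — the construction behind features such as "mean
2–4 Hz power during inhalation".

Per-measurement feature vectors are the mean over that measurement's
quality-passing buffers.  Missing cells (a phase with no spectrogram
frames) are NaN and are imputed later, inside cross-validation, with
training-fold column medians.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landmarks import (
    LandmarkSet,
    SignalBuffer,
    Spectrogram,
    butterworth_filter,
    compute_spectrogram,
    detect_landmarks,
    signal_envelope,
    split_buffers,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureVector",
    "BandPhaseGrid",
    "DEFAULT_BANDS",
    "time_domain_features",
    "frequency_domain_features",
    "extract_measurement_features",
    "assemble_feature_matrix",
    "impute_with_medians",
]

DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (0.5, 1.0),
    (1.0, 2.0),
    (2.0, 4.0),
    (4.0, 8.0),
    (8.0, 16.0),
    (16.0, 32.0),
    (32.0, 64.0),
)

TIME_FEATURE_NAMES = [
    "rr_mean_s",
    "rr_sd_s",
    "rr_cv",
    "bpm",
    "s1s2_mean_s",
    "s1s2_sd_s",
    "s2s1_mean_s",
    "s2s1_sd_s",
    "s1_amp_mean",
    "s1_amp_sd",
    "s2_amp_mean",
    "s2_amp_sd",
    "s2s1_amp_ratio",
    "breaths_per_min",
    "inhale_exhale_ratio",
]


@dataclass
class FeatureVector:
    measurement_id: str
    values: dict[str, float]
    quality_ok: bool = True


@dataclass
class BandPhaseGrid:
    """Frequency bands × respiratory phases used to section the spectrogram."""

    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    phases: tuple[str, ...] = ("inhale", "exhale", "full")

    def validate(self, nyquist: float | None = None) -> None:
        prev_hi = 0.0
        for lo, hi in self.bands:
            if not (lo < hi):
                raise ValueError(f"band ({lo}, {hi}) not increasing")
            if lo < prev_hi:
                raise ValueError("bands overlap or are out of order")
            prev_hi = hi
        if nyquist is not None and prev_hi > nyquist:
            raise ValueError("band grid exceeds Nyquist frequency")

    def feature_names(self) -> list[str]:
        names = [
            f"band_{lo:g}_{hi:g}Hz_{phase}" for lo, hi in self.bands for phase in self.phases
        ]
        names += [f"band_{lo:g}_{hi:g}Hz_ie_ratio" for lo, hi in self.bands]
        return names


def _stat_pair(x: np.ndarray) -> tuple[float, float]:
    # SD of a single observation is defined as 0 (degenerate-n rule),
    # keeping vectors complete for single-beat buffers.
    if len(x) == 0:
        return np.nan, np.nan
    return float(np.mean(x)), float(np.std(x)) if len(x) > 1 else 0.0


def time_domain_features(
    b: SignalBuffer,
    lm: LandmarkSet,
    hp_cutoff: float = 15.0,
    smooth_ms: float = 20.0,
) -> FeatureVector:
    """Distances and mean amplitudes between landmarks for one buffer."""
    values = {name: np.nan for name in TIME_FEATURE_NAMES}
    if not lm.quality_ok:
        return FeatureVector(b.measurement_id, values, quality_ok=False)

    s1 = np.asarray(lm.s1_times, dtype=float)
    s2 = np.asarray(lm.s2_times, dtype=float)
    npair = min(len(s1), len(s2))
    rr = np.diff(s1)
    s1s2 = s2[:npair] - s1[:npair]
    s2s1 = s1[1:npair] - s2[: npair - 1] if npair >= 2 else np.empty(0)

    values["rr_mean_s"], values["rr_sd_s"] = _stat_pair(rr)
    values["s1s2_mean_s"], values["s1s2_sd_s"] = _stat_pair(s1s2)
    values["s2s1_mean_s"], values["s2s1_sd_s"] = _stat_pair(s2s1)
    values["rr_cv"] = values["rr_sd_s"] / values["rr_mean_s"] if values["rr_mean_s"] else np.nan
    values["bpm"] = 60.0 / values["rr_mean_s"] if values["rr_mean_s"] else np.nan

    env = signal_envelope(butterworth_filter(b.samples, b.fs, hp_cutoff, "highpass"), b.fs, smooth_ms)

    def env_at(times: np.ndarray) -> np.ndarray:
        idx = np.clip(np.round((times - b.start_time) * b.fs).astype(int), 0, len(env) - 1)
        return env[idx]

    a1, a2 = env_at(s1), env_at(s2)
    values["s1_amp_mean"], values["s1_amp_sd"] = _stat_pair(a1)
    values["s2_amp_mean"], values["s2_amp_sd"] = _stat_pair(a2)
    values["s2s1_amp_ratio"] = (
        values["s2_amp_mean"] / values["s1_amp_mean"] if values["s1_amp_mean"] else np.nan
    )

    inhale_len = np.array([e - a for a, e in lm.inhale_intervals])
    exhale_len = np.array([e - a for a, e in lm.exhale_intervals])
    n_breaths = 0.5 * (len(inhale_len) + len(exhale_len))
    values["breaths_per_min"] = 60.0 * n_breaths / b.duration
    values["inhale_exhale_ratio"] = (
        float(np.mean(inhale_len) / np.mean(exhale_len)) if len(exhale_len) else np.nan
    )
    return FeatureVector(b.measurement_id, values, quality_ok=True)


def _frames_in_intervals(times: np.ndarray, intervals) -> np.ndarray:
    mask = np.zeros(len(times), dtype=bool)
    for a, b in intervals:
        mask |= (times >= a) & (times < b)
    return mask


def frequency_domain_features(
    sg: Spectrogram, lm: LandmarkSet, grid: BandPhaseGrid | None = None
) -> FeatureVector:
    """Mean spectral power per (band, phase) cross-section, + band ratios.

    A phase with zero spectrogram frames leaves its cells as NaN (the
    missing marker); quality is unaffected unless >20% of cells are
    missing.
    """
    grid = grid or BandPhaseGrid()
    grid.validate()
    phase_masks = {
        "inhale": _frames_in_intervals(sg.times, lm.inhale_intervals),
        "exhale": _frames_in_intervals(sg.times, lm.exhale_intervals),
        "full": np.ones(len(sg.times), dtype=bool),
    }
    values: dict[str, float] = {}
    for lo, hi in grid.bands:
        fmask = (sg.freqs >= lo) & (sg.freqs < hi)
        cells = {}
        for phase in grid.phases:
            tmask = phase_masks[phase]
            if not fmask.any() or not tmask.any():
                cells[phase] = np.nan
            else:
                cells[phase] = float(np.mean(sg.power[np.ix_(fmask, tmask)]))
            values[f"band_{lo:g}_{hi:g}Hz_{phase}"] = cells[phase]
        inh, exh = cells.get("inhale", np.nan), cells.get("exhale", np.nan)
        values[f"band_{lo:g}_{hi:g}Hz_ie_ratio"] = inh / exh if exh and np.isfinite(exh) else np.nan
    n_missing = sum(1 for v in values.values() if not np.isfinite(v))
    quality = n_missing < 0.2 * len(values)
    return FeatureVector("", values, quality_ok=quality)


def extract_measurement_features(measurement, config=None, grid: BandPhaseGrid | None = None) -> FeatureVector:
    """Feature vector for one measurement: mean over quality-passing buffers."""
    from .config import PipelineConfig

    cfg = config or PipelineConfig()
    grid = grid or BandPhaseGrid(bands=tuple(tuple(b) for b in cfg.bands))
    duration = measurement.duration
    buffer_s = min(cfg.buffer_s, duration)
    buffers = split_buffers(measurement, buffer_s=buffer_s, step_s=cfg.step_s)
    rows = []
    for b in buffers:
        lm = detect_landmarks(b, cfg)
        if not lm.quality_ok:
            continue
        tf = time_domain_features(b, lm, hp_cutoff=cfg.hp_cutoff, smooth_ms=cfg.smooth_ms)
        sg = compute_spectrogram(b, window_s=cfg.window_s, overlap_frac=cfg.overlap_frac)
        ff = frequency_domain_features(sg, lm, grid)
        if tf.quality_ok:
            rows.append({**tf.values, **ff.values})
    if not rows:
        names = TIME_FEATURE_NAMES + grid.feature_names()
        return FeatureVector(measurement.measurement_id, {k: np.nan for k in names}, quality_ok=False)
    df = pd.DataFrame(rows)
    agg = df.median() if cfg.buffer_aggregation == "median" else df.mean()
    return FeatureVector(measurement.measurement_id, agg.to_dict(), quality_ok=True)


def assemble_feature_matrix(
    measurements, labels: dict[str, int] | None = None, config=None
) -> tuple[pd.DataFrame, list[str]]:
    """Per-measurement feature matrix for a cohort.

    Returns (DataFrame indexed by measurement_id with a leading
    ``subject_id`` column and deterministic feature columns, excluded
    measurement ids).  Measurements with zero usable buffers are excluded
    and logged.
    """
    rows, index, subjects, excluded = [], [], [], []
    for m in measurements:
        fv = extract_measurement_features(m, config)
        if not fv.quality_ok:
            excluded.append(m.measurement_id)
            logger.warning("measurement %s excluded: no usable buffers", m.measurement_id)
            continue
        rows.append(fv.values)
        index.append(m.measurement_id)
        subjects.append(m.subject_id)
    df = pd.DataFrame(rows, index=pd.Index(index, name="measurement_id"))
    df.insert(0, "subject_id", subjects)
    if labels is not None:
        df.insert(1, "label", [labels[m] for m in index])
    return df, excluded


def impute_with_medians(X: np.ndarray, medians: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Median-impute NaNs column-wise; never alters non-missing values.

    ``medians`` computed on a training fold can be re-applied to held-out
    data so no information leaks across the split.
    """
    X = np.array(X, dtype=float, copy=True)
    if medians is None:
        with np.errstate(all="ignore"):
            medians = np.nanmedian(X, axis=0)
        medians = np.where(np.isfinite(medians), medians, 0.0)
    mask = ~np.isfinite(X)
    if mask.any():
        X[mask] = np.broadcast_to(medians, X.shape)[mask]
    return X, medians
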