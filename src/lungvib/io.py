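"""File I/O: WAV/CSV signals, cohort tables, landmark JSON, artifacts.

Signals travel as single-channel float32 WAV (sampling rate in the
header) or one-column CSV with a JSON sidecar carrying the rate.  Cohort
tables are plain CSV; ground-truth landmarks round-trip through JSON.
Every simulated cohort directory gets a manifest with per-file SHA-256
checksums so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .cohort import SubjectRecord, VibrationMeasurement
from .landmarks import LandmarkSet

COHORT_COLUMNS = [
    "subject_id",
    "measurement_id",
    "label",
    "age",
    "sex",
    "bmi",
    "heart_failure",
    "respiratory_condition",
    "valvular_disorder",
    "wav_path",
]


def write_wav(path, samples: np.ndarray, fs: float) -> None:
    wavfile.write(str(path), int(round(fs)), np.asarray(samples, dtype=np.float32))


def read_wav(path) -> tuple[np.ndarray, float]:
    fs, data = wavfile.read(str(path))
    return np.asarray(data, dtype=float), float(fs)


def write_signal_csv(path, samples: np.ndarray, fs: float) -> None:
    np.savetxt(str(path), np.asarray(samples, dtype=float), fmt="%.8g")
    Path(str(path) + ".json").write_text(json.dumps({"fs": fs}))


def read_signal_csv(path) -> tuple[np.ndarray, float]:
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    return np.loadtxt(str(path)), float(sidecar["fs"])


def write_landmarks(path, lm: LandmarkSet) -> None:
    Path(path).write_text(json.dumps(lm.to_dict(), indent=1))


def read_landmarks(path) -> LandmarkSet:
    return LandmarkSet.from_dict(json.loads(Path(path).read_text()))


def write_cohort(
    out_dir, subjects: list[SubjectRecord], measurements: list[VibrationMeasurement]
) -> Path:
    """Persist a cohort: WAVs + truth JSON + cohort CSV + checksum manifest."""
    out = Path(out_dir)
    sig_dir = out / "signals"
    sig_dir.mkdir(parents=True, exist_ok=True)
    by_subject = {s.subject_id: s for s in subjects}
    rows = []
    for m in measurements:
        s = by_subject[m.subject_id]
        wav = sig_dir / f"{m.measurement_id}.wav"
        write_wav(wav, m.samples, m.fs)
        if m.truth_landmarks is not None:
            write_landmarks(sig_dir / f"{m.measurement_id}.landmarks.json", m.truth_landmarks)
        rows.append(
            {
                "subject_id": s.subject_id,
                "measurement_id": m.measurement_id,
                "label": int(s.congested),
                "age": round(s.age, 2),
                "sex": s.sex,
                "bmi": round(s.bmi, 2),
                "heart_failure": int(s.heart_failure_history),
                "respiratory_condition": int(s.respiratory_condition),
                "valvular_disorder": int(s.valvular_disorder),
                "wav_path": str(wav.relative_to(out)),
            }
        )
    table = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    table.to_csv(out / "cohort.csv", index=False)
    write_manifest(out)
    return out / "cohort.csv"


def read_cohort(cohort_dir) -> tuple[pd.DataFrame, list[VibrationMeasurement]]:
    """Load a persisted cohort table and its signals (+ truth landmarks)."""
    cohort_dir = Path(cohort_dir)
    csv = cohort_dir / "cohort.csv"
    if not csv.exists():
        raise FileNotFoundError(f"no cohort.csv under {cohort_dir}")
    table = pd.read_csv(csv)
    measurements = []
    for _, row in table.iterrows():
        wav = cohort_dir / row["wav_path"]
        if not wav.exists():
            raise FileNotFoundError(f"missing signal file for {row['measurement_id']}: {wav}")
        samples, fs = read_wav(wav)
        lm_path = wav.parent / f"{row['measurement_id']}.landmarks.json"
        truth = read_landmarks(lm_path) if lm_path.exists() else None
        measurements.append(
            VibrationMeasurement(
                subject_id=row["subject_id"],
                measurement_id=row["measurement_id"],
                fs=fs,
                samples=samples,
                truth_landmarks=truth,
            )
        )
    return table, measurements


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(directory) -> Path:
    directory = Path(directory)
    entries = {}
    for p in sorted(directory.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            entries[str(p.relative_to(directory))] = sha256_file(p)
    out = directory / "manifest.json"
    out.write_text(json.dumps(entries, indent=1, sort_keys=True))
    return out


def report_to_markdown(report) -> str:
    """Markdown table mirroring the diagnostic panel layout."""
    rows = [
        ("Sensitivity", "sensitivity"),
        ("Specificity", "specificity"),
        ("Balanced accuracy", "balanced_accuracy"),
        ("AUC", "auc"),
        ("PPV (sample)", "ppv_sample"),
        ("NPV (sample)", "npv_sample"),
        (f"PPV ({report.external_prevalence:.0%})", "ppv_at_p"),
        (f"NPV ({report.external_prevalence:.0%})", "npv_at_p"),
        ("PLR", "plr"),
        ("NLR", "nlr"),
    ]
    lines = ["| Variable | Point estimate (95% CI) |", "| --- | --- |"]
    for label, key in rows:
        v = getattr(report, key)
        ci = report.cis.get(key)
        ci_txt = f" ({ci[0]:.2f}, {ci[1]:.2f})" if ci else ""
        lines.append(f"| {label} | {v:.2f}{ci_txt} |")
    lines.append(f"| Inconclusive fraction | {report.na_fraction:.3f} |")
    return "\n".join(lines) + "\n"
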