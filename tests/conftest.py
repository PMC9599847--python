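"""Shared fixtures: small synthetic cohorts run through the full pipeline.

The heavier end-to-end fixtures are session-scoped so the planted-effect
and null cohorts are simulated and cross-validated once and reused by
several tests.
"""

import numpy as np
import pytest

import lungvib as lv
from lungvib.config import PipelineConfig
from lungvib.model import CongestionModel


def build_fit(n_subjects, effect, seed, n_boot=100, duration=120.0, k_folds=10):
    subjects = lv.generate_cohort(n_subjects, 0.5, 1, seed=seed)
    sig = lv.SignalModelConfig(duration=duration, congestion_effect=effect, seed=seed)
    measurements = lv.generate_measurements(subjects, sig)
    cfg = PipelineConfig(n_boot=n_boot, seed=seed, k_folds=k_folds)
    model = CongestionModel.from_measurements(measurements, subjects, cfg)
    return model, model.fit(seed=seed)


@pytest.fixture(scope="session")
def planted_fit():
    """100-subject cohort with planted congestion effect 3, grouped 10-fold CV."""
    return build_fit(100, 3.0, seed=1, n_boot=200)


@pytest.fixture(scope="session")
def null_fit():
    """60-subject cohort with the congestion effect switched off."""
    return build_fit(60, 0.0, seed=1, n_boot=50)


@pytest.fixture(scope="session")
def control_measurement():
    """One noise-free-ish control measurement at default settings, 60 s."""
    subj = lv.SubjectRecord("S000", False, 70.0, "M", 28.0, False, False, False)
    cfg = lv.SignalModelConfig(duration=60.0)
    return lv.synthesize_measurement(subj, cfg), cfg


@pytest.fixture(scope="session")
def sweep_table():
    """Duration sweep on a compact planted cohort (16 subjects, 8 folds)."""
    model, res = build_fit(16, 3.0, seed=21, n_boot=20, k_folds=8)
    return res.duration_sweep()
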