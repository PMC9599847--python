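"""Model/Results interface over the congestion-screening pipeline.

``CongestionModel`` is constructed from a per-measurement feature matrix
(or directly from raw measurements, which are then passed through the
landmark/feature pipeline) and ``fit()`` runs the subject-grouped
cross-validated evaluation, returning a ``CongestionResults`` carrying
the out-of-fold scores, the diagnostic report with bootstrap confidence
intervals, a final deployable stump ensemble trained on all data, and a
``summary()`` table.

Example
-------
>>> subjects = generate_cohort(60, 0.5, seed=7)
>>> cfg = SignalModelConfig(congestion_effect=3.0, seed=7)
>>> measurements = generate_measurements(subjects, cfg)
>>> res = CongestionModel.from_measurements(measurements, subjects).fit(seed=7)
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boost import (
    ScoreOutput,
    StumpEnsemble,
    calibrate_na_zone,
    select_operating_point,
    train_adaboost,
)
from .config import PipelineConfig
from .evaluate import (
    DiagnosticReport,
    covariate_effect_table,
    cross_validated_scores,
    duration_sweep,
    evaluate_scores,
)
from .features import assemble_feature_matrix, impute_with_medians

__all__ = ["CongestionModel", "CongestionResults"]


class CongestionModel:
    """Congestion screening model over a cohort feature matrix.

    Parameters
    ----------
    features : DataFrame, one row per measurement, feature columns only.
    labels : boolean/0-1 array aligned with ``features`` rows.
    subject_ids : subject of each measurement (grouping unit for CV and
        bootstrap).
    config : PipelineConfig, validated on construction.
    """

    def __init__(self, features: pd.DataFrame, labels, subject_ids, config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()
        self.config.validate()
        self.features = features
        self.labels = np.asarray(labels).astype(bool)
        self.subject_ids = np.asarray(subject_ids)
        if len(self.features) != len(self.labels) or len(self.labels) != len(self.subject_ids):
            raise ValueError("features, labels and subject_ids must align")
        if self.labels.all() or not self.labels.any():
            raise ValueError("both classes must be present")
        self.measurements = None  # raw signals, if built from measurements
        self.excluded: list[str] = []

    @classmethod
    def from_measurements(cls, measurements, subjects, config: PipelineConfig | None = None) -> "CongestionModel":
        """Build from raw vibration measurements + subject records."""
        cfg = config or PipelineConfig()
        label_of = {s.subject_id: int(s.congested) for s in subjects}
        labels_by_m = {m.measurement_id: label_of[m.subject_id] for m in measurements}
        feats, excluded = assemble_feature_matrix(measurements, config=cfg)
        subj = feats["subject_id"].to_numpy()
        lab = np.array([labels_by_m[m] for m in feats.index])
        model = cls(feats.drop(columns=["subject_id"]), lab, subj, cfg)
        model.measurements = list(measurements)
        model._labels_by_measurement = labels_by_m
        model.excluded = excluded
        return model

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "label",
        subject_col: str = "subject_id",
        config: PipelineConfig | None = None,
    ) -> "CongestionModel":
        """Build from a flat table with label and subject columns."""
        feature_cols = [c for c in df.columns if c not in (label_col, subject_col)]
        return cls(df[feature_cols], df[label_col].to_numpy(), df[subject_col].to_numpy(), config)

    def fit(self, seed: int | None = None) -> "CongestionResults":
        """Cross-validated evaluation plus a final full-data ensemble."""
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        outputs, scores = cross_validated_scores(
            self.features, self.labels, self.subject_ids, cfg, seed=seed
        )
        report = evaluate_scores(outputs, scores, self.labels, self.subject_ids, cfg, seed=seed)
        X, med = impute_with_medians(self.features.to_numpy(dtype=float))
        y = np.where(self.labels, 1.0, -1.0)
        ensemble, trace = train_adaboost(
            X, y, list(self.features.columns), n_rounds=cfg.n_rounds, eps_floor=cfg.eps_floor
        )
        s_full = ensemble.scores(X)
        theta = select_operating_point(s_full, self.labels)
        ensemble.operating_threshold = theta
        ensemble.na_zone = calibrate_na_zone(s_full, self.labels, theta, cfg.max_na_frac)
        return CongestionResults(
            model=self,
            ensemble=ensemble,
            training_trace=trace,
            imputation_medians=med,
            cv_outputs=outputs,
            cv_scores=scores,
            report=report,
            seed=seed,
        )


@dataclass
class CongestionResults:
    """Fit artifacts: out-of-fold scores, diagnostic report, final model."""

    model: CongestionModel
    ensemble: StumpEnsemble
    training_trace: object
    imputation_medians: np.ndarray
    cv_outputs: list[ScoreOutput]
    cv_scores: np.ndarray
    report: DiagnosticReport
    seed: int = 0

    @property
    def auc(self) -> float:
        return self.report.auc

    @property
    def na_fraction(self) -> float:
        return self.report.na_fraction

    def covariate_effects(self, covariates: pd.DataFrame):
        """Misclassification-vs-covariate screen on the CV outputs."""
        return covariate_effect_table(self.cv_outputs, self.model.labels, covariates)

    def duration_sweep(self, durations=None) -> pd.DataFrame:
        if self.model.measurements is None:
            raise RuntimeError("duration sweep needs raw measurements; build via from_measurements")
        return duration_sweep(
            self.model.measurements,
            self.model._labels_by_measurement,
            self.model.config,
            durations=durations,
            seed=self.seed,
        )

    def score_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "measurement_id": [o.measurement_id if o else "" for o in self.cv_outputs],
                "subject_id": self.model.subject_ids,
                "label": self.model.labels.astype(int),
                "score": self.cv_scores,
                "decision": [o.decision if o else "unscored" for o in self.cv_outputs],
            }
        )

    def summary(self) -> str:
        """Text panel of the diagnostic metrics with 95% bootstrap CIs."""
        from statsmodels.iolib.table import SimpleTable

        rep = self.report
        labels = {
            "sensitivity": "Sensitivity",
            "specificity": "Specificity",
            "balanced_accuracy": "Balanced accuracy",
            "auc": "AUC",
            "ppv_sample": "PPV (sample prevalence)",
            "npv_sample": "NPV (sample prevalence)",
            "ppv_at_p": f"PPV ({rep.external_prevalence:.0%} prevalence)",
            "npv_at_p": f"NPV ({rep.external_prevalence:.0%} prevalence)",
            "plr": "Positive likelihood ratio",
            "nlr": "Negative likelihood ratio",
        }
        rows = []
        for key, lab in labels.items():
            val = getattr(rep, key)
            ci = rep.cis.get(key)
            ci_txt = f"({ci[0]:.3g}, {ci[1]:.3g})" if ci else "--"
            rows.append([lab, f"{val:.3g}", ci_txt])
        rows.append(["Inconclusive (NA) fraction", f"{rep.na_fraction:.3g}", "--"])
        n = len(self.model.labels)
        n_sub = len(set(self.model.subject_ids.tolist()))
        title = (
            f"Lung-congestion screening: grouped {self.model.config.k_folds}-fold CV, "
            f"{n} measurements / {n_sub} subjects"
        )
        table = SimpleTable(rows, headers=["Metric", "Estimate", "95% CI"], title=title)
        return table.as_text()
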