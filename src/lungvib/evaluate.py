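"""Diagnostic-accuracy evaluation of the congestion scorer.

Implements the full evaluation protocol: subject-grouped k-fold
cross-validation (all measurements of one subject stay in the same fold),
ROC/AUC, the diagnostic-metric panel (sensitivity, specificity, balanced
accuracy, predictive values at both the sample prevalence and an external
prevalence, likelihood ratios), subject-level bootstrap confidence
intervals, the measurement-duration sweep, and the covariate screen
(Fisher's exact test for binary covariates, two-sample Kolmogorov–Smirnov
for continuous ones, no multiple-testing correction).

Note on predictive values: at the *sample* prevalence the Bayes identity
PPV = Se·p̂/(Se·p̂ + (1−Sp)(1−p̂)) with p̂ = (tp+fn)/n reduces exactly to the
raw-count PPV = tp/(tp+fp), so only the external-prevalence values need
the identity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .boost import (
    ScoreOutput,
    StumpEnsemble,
    balanced_accuracy,
    calibrate_na_zone,
    select_operating_point,
    train_adaboost,
)
from .config import PipelineConfig
from .features import assemble_feature_matrix, impute_with_medians

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "DiagnosticReport",
    "CovariateEffectRow",
    "grouped_kfold",
    "cross_validated_scores",
    "roc_curve",
    "confusion_counts",
    "diagnostic_metrics",
    "bootstrap_ci",
    "evaluate_scores",
    "duration_sweep",
    "fisher_exact",
    "ks_two_sample",
    "covariate_effect_table",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    n_inconclusive: int = 0

    @property
    def n_conclusive(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class DiagnosticReport:
    """The diagnostic-metric panel with 95% bootstrap CIs."""

    sensitivity: float
    specificity: float
    balanced_accuracy: float
    auc: float
    ppv_sample: float
    npv_sample: float
    ppv_at_p: float
    npv_at_p: float
    plr: float
    nlr: float
    na_fraction: float
    external_prevalence: float = 0.32
    cis: dict[str, tuple[float, float]] = field(default_factory=dict)

    METRICS = (
        "sensitivity",
        "specificity",
        "balanced_accuracy",
        "auc",
        "ppv_sample",
        "npv_sample",
        "ppv_at_p",
        "npv_at_p",
        "plr",
        "nlr",
    )

    def to_dict(self) -> dict:
        d = {m: getattr(self, m) for m in self.METRICS}
        d["na_fraction"] = self.na_fraction
        d["external_prevalence"] = self.external_prevalence
        d["cis"] = {k: list(v) for k, v in self.cis.items()}
        return d


@dataclass
class CovariateEffectRow:
    covariate: str
    test: str  # "fisher_exact" | "ks_two_sample" | "not_computable"
    statistic: float
    p_value: float
    note: str = ""


def grouped_kfold(subject_ids, k: int = 10, seed: int = 0) -> dict[str, int]:
    """Assign each subject to one of k folds (shuffle, then deal round-robin).

    Fold sizes differ by at most one; every measurement later inherits its
    subject's fold, so repeated measurements never straddle train/test.
    """
    subjects = sorted(set(subject_ids))
    if k > len(subjects):
        raise ValueError(f"k={k} exceeds number of subjects ({len(subjects)})")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    return {subjects[j]: i % k for i, j in enumerate(order)}


def cross_validated_scores(
    features: pd.DataFrame,
    labels: np.ndarray,
    subject_ids,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> tuple[list[ScoreOutput], np.ndarray]:
    """Out-of-fold congestion scores under subject-grouped k-fold CV.

    Within each fold, median imputation, boosting, operating-point
    selection and NA-zone calibration all use the training split only;
    the held-out fold is then scored once.  Returns the per-measurement
    ScoreOutput list (aligned with ``features``) and the raw score array.
    """
    cfg = config or PipelineConfig()
    seed = cfg.seed if seed is None else seed
    X_all = features.to_numpy(dtype=float)
    names = list(features.columns)
    labels = np.asarray(labels).astype(bool)
    subject_ids = np.asarray(subject_ids)
    fold_of = grouped_kfold(subject_ids, k=cfg.k_folds, seed=seed)
    folds = np.array([fold_of[s] for s in subject_ids])
    outputs: list[ScoreOutput | None] = [None] * len(labels)
    scores = np.full(len(labels), np.nan)
    y = np.where(labels, 1.0, -1.0)
    for f in range(cfg.k_folds):
        test = folds == f
        train = ~test
        if not test.any():
            continue
        if labels[train].all() or not labels[train].any():
            warnings.warn(f"fold {f} skipped: single-class training split")
            continue
        X_train, med = impute_with_medians(X_all[train])
        X_test, _ = impute_with_medians(X_all[test], med)
        model, _ = train_adaboost(
            X_train, y[train], names, n_rounds=cfg.n_rounds, eps_floor=cfg.eps_floor
        )
        s_train = model.scores(X_train)
        theta = select_operating_point(s_train, labels[train])
        zone = calibrate_na_zone(s_train, labels[train], theta, cfg.max_na_frac)
        s_test = model.scores(X_test)
        for idx, s in zip(np.nonzero(test)[0], s_test):
            if zone[0] < s < zone[1]:
                decision = "inconclusive"
            elif s >= theta:
                decision = "case"
            else:
                decision = "control"
            outputs[idx] = ScoreOutput(str(features.index[idx]), float(s), decision)
            scores[idx] = s
    kept = [o for o in outputs if o is not None]
    if len(kept) < len(outputs):
        logger.warning("%d measurements left unscored by skipped folds", len(outputs) - len(kept))
    return [o for o in outputs], scores


def roc_curve(scores, labels) -> tuple[np.ndarray, float]:
    """ROC operating points at every distinct threshold, and trapezoid AUC.

    With ties handled by blocks, the trapezoid AUC equals the
    Mann–Whitney U probability P(score_case > score_control) + ½·ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s, lab = scores[order], labels[order]
    npos, nneg = labels.sum(), (~labels).sum()
    tp = np.cumsum(lab)
    fp = np.cumsum(~lab)
    distinct = np.nonzero(np.diff(s))[0]
    idx = np.concatenate((distinct, [len(s) - 1]))
    tpr = np.concatenate(([0.0], tp[idx] / npos))
    fpr = np.concatenate(([0.0], fp[idx] / nneg))
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack((fpr, tpr)), auc


def confusion_counts(outputs, labels, na_policy: str = "exclude") -> ConfusionCounts:
    """Tally a confusion table under the chosen inconclusive policy.

    ``exclude`` drops inconclusives from the table (still counted in
    ``n_inconclusive``); ``count_as_error`` scores an inconclusive case as
    a false negative and an inconclusive control as a false positive —
    the worst-case reading in which a non-answer is a miss.
    """
    if na_policy not in ("exclude", "count_as_error"):
        raise ValueError(f"unknown na_policy {na_policy!r}")
    c = ConfusionCounts()
    for out, lab in zip(outputs, labels, strict=True):
        if out is None:
            continue
        truth = bool(lab)
        if out.decision == "inconclusive":
            c.n_inconclusive += 1
            if na_policy == "count_as_error":
                if truth:
                    c.fn += 1
                else:
                    c.fp += 1
            continue
        pred = out.decision == "case"
        if pred and truth:
            c.tp += 1
        elif pred and not truth:
            c.fp += 1
        elif not pred and truth:
            c.fn += 1
        else:
            c.tn += 1
    return c


def diagnostic_metrics(c: ConfusionCounts, external_prevalence: float = 0.32) -> DiagnosticReport:
    """Point estimates of the diagnostic panel from a confusion table."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("both classes must be present among conclusive outputs")
    se = c.tp / (c.tp + c.fn)
    sp = c.tn / (c.tn + c.fp)
    p = external_prevalence
    ppv_p = se * p / (se * p + (1 - sp) * (1 - p)) if (se * p + (1 - sp) * (1 - p)) > 0 else np.nan
    npv_p = sp * (1 - p) / (sp * (1 - p) + (1 - se) * p) if (sp * (1 - p) + (1 - se) * p) > 0 else np.nan
    total = c.n_conclusive + c.n_inconclusive
    return DiagnosticReport(
        sensitivity=se,
        specificity=sp,
        balanced_accuracy=(se + sp) / 2.0,
        auc=np.nan,
        ppv_sample=c.tp / (c.tp + c.fp) if c.tp + c.fp > 0 else np.nan,
        npv_sample=c.tn / (c.tn + c.fn) if c.tn + c.fn > 0 else np.nan,
        ppv_at_p=ppv_p,
        npv_at_p=npv_p,
        plr=se / (1 - sp) if sp < 1 else np.inf,
        nlr=(1 - se) / sp if sp > 0 else np.inf,
        na_fraction=c.n_inconclusive / total if total else np.nan,
        external_prevalence=p,
    )


@dataclass
class CIResult:
    lo: float
    hi: float
    n_failed: int = 0
    ok: bool = True


def bootstrap_ci(
    statistic,
    subject_ids,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> CIResult:
    """Percentile bootstrap CI, resampling subjects with replacement.

    ``statistic`` receives an index array over measurements; all
    measurements of a resampled subject travel together, respecting the
    repeated-measurement clustering.  Resamples on which the statistic is
    undefined are skipped; if more than 20% fail the CI is reported as
    failed.
    """
    subject_ids = np.asarray(subject_ids)
    subjects = np.array(sorted(set(subject_ids.tolist())))
    idx_of = {s: np.nonzero(subject_ids == s)[0] for s in subjects}
    rng = np.random.default_rng(seed)
    vals, n_failed = [], 0
    for _ in range(n_boot):
        picked = rng.choice(subjects, size=len(subjects), replace=True)
        idx = np.concatenate([idx_of[s] for s in picked])
        try:
            v = statistic(idx)
        except (ValueError, ZeroDivisionError):
            v = np.nan
        if v is None or not np.isfinite(v):
            n_failed += 1
        else:
            vals.append(float(v))
    if n_failed > 0.2 * n_boot:
        return CIResult(np.nan, np.nan, n_failed=n_failed, ok=False)
    a = (1 - level) / 2
    lo, hi = np.percentile(vals, [100 * a, 100 * (1 - a)])
    return CIResult(float(lo), float(hi), n_failed=n_failed, ok=True)


def evaluate_scores(
    outputs,
    scores,
    labels,
    subject_ids,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> DiagnosticReport:
    """Full diagnostic report (point estimates + bootstrap CIs) from
    out-of-fold score outputs."""
    cfg = config or PipelineConfig()
    seed = cfg.seed if seed is None else seed
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    outputs = list(outputs)
    c = confusion_counts(outputs, labels, cfg.na_policy)
    report = diagnostic_metrics(c, cfg.external_prevalence)
    _, report.auc = roc_curve(scores[np.isfinite(scores)], labels[np.isfinite(scores)])

    def metric_stat(name):
        def stat(idx):
            sub_out = [outputs[i] for i in idx]
            sub_lab = labels[idx]
            if name == "auc":
                s = scores[idx]
                m = np.isfinite(s)
                _, a = roc_curve(s[m], sub_lab[m])
                return a
            cc = confusion_counts(sub_out, sub_lab, cfg.na_policy)
            rep = diagnostic_metrics(cc, cfg.external_prevalence)
            return getattr(rep, name)

        return stat

    for name in DiagnosticReport.METRICS:
        ci = bootstrap_ci(metric_stat(name), subject_ids, n_boot=cfg.n_boot, seed=seed)
        if ci.ok:
            report.cis[name] = (ci.lo, ci.hi)
    return report


def duration_sweep(
    measurements,
    labels_by_measurement: dict[str, int],
    config: PipelineConfig | None = None,
    durations=None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Re-run the cross-validated evaluation on cropped measurements.

    Every measurement is cropped to its first ``d`` seconds for each
    duration d in 30…120 s by 5 s (19 rows); buffering adapts to the crop
    (buffer length = min(configured buffer, d)).  Metrics use the per-fold
    maximal-balanced-accuracy operating points, as in the main run.
    """
    cfg = config or PipelineConfig()
    seed = cfg.seed if seed is None else seed
    durations = np.arange(30, 125, 5) if durations is None else np.asarray(durations)
    max_d = float(durations.max())
    for m in measurements:
        if m.duration + 1e-9 < max_d:
            raise ValueError(f"measurement {m.measurement_id} shorter than {max_d} s")
    rows = []
    for d in durations:
        cropped = [m.cropped(float(d)) for m in measurements]
        feats, _ = assemble_feature_matrix(cropped, config=cfg)
        subj = feats["subject_id"].to_numpy()
        X = feats.drop(columns=["subject_id"])
        lab = np.array([labels_by_measurement[m] for m in feats.index]).astype(bool)
        outputs, scores = cross_validated_scores(X, lab, subj, cfg, seed=seed)
        c = confusion_counts(outputs, lab, cfg.na_policy)
        rep = diagnostic_metrics(c, cfg.external_prevalence)
        m_ok = np.isfinite(scores)
        _, auc = roc_curve(scores[m_ok], lab[m_ok])
        rows.append(
            {
                "duration_s": float(d),
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
                "balanced_accuracy": rep.balanced_accuracy,
                "auc": auc,
                "na_fraction": rep.na_fraction,
            }
        )
    return pd.DataFrame(rows)


def fisher_exact(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2×2 table [[a, b], [c, d]].

    The p-value sums hypergeometric probabilities (margins fixed) of all
    tables no more probable than the observed one; the odds ratio is
    ad/bc with 0/inf markers for empty cells.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        raise ValueError("degenerate margin")
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = stats.hypergeom.pmf(a, n, c1, r1)
    p = float(np.sum(pmf[pmf <= p_obs + 1e-12]))
    if b * c == 0:
        oratio = np.inf if a * d > 0 else (0.0 if a * d == 0 and b * c == 0 and (b or c) else np.nan)
        if a * d == 0 and b * c == 0:
            oratio = np.nan
    else:
        oratio = a * d / (b * c)
    return float(oratio), min(p, 1.0)


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test (exact D, asymptotic p).

    D is the maximal absolute ECDF difference over the pooled order
    statistics; the p-value uses the asymptotic Kolmogorov distribution
    with effective n = n_x·n_y/(n_x+n_y).
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate((x, y))
    cdf_x = np.searchsorted(x, pooled, side="right") / len(x)
    cdf_y = np.searchsorted(y, pooled, side="right") / len(y)
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    ne = len(x) * len(y) / (len(x) + len(y))
    p = float(special.kolmogorov(np.sqrt(ne) * d))
    return d, min(max(p, 0.0), 1.0)


def covariate_effect_table(outputs, labels, covariates: pd.DataFrame) -> list[CovariateEffectRow]:
    """Screen covariates for association with misclassification.

    Conclusive predictions are marked correct/misclassified; binary
    covariates get Fisher's exact test on the 2×2 misclassified×covariate
    table, continuous ones a two-sample KS comparing covariate values of
    misclassified vs correct.  No multiple-testing correction is applied.
    """
    labels = np.asarray(labels).astype(bool)
    conclusive = np.array(
        [o is not None and o.decision != "inconclusive" for o in outputs]
    )
    correct = np.array(
        [
            o is not None and ((o.decision == "case") == bool(lab))
            for o, lab in zip(outputs, labels)
        ]
    )
    mis = conclusive & ~correct
    ok = conclusive & correct
    rows: list[CovariateEffectRow] = []
    no_errors = mis.sum() == 0
    for name in sorted(covariates.columns):
        col = covariates[name]
        if no_errors:
            rows.append(CovariateEffectRow(name, "not_computable", np.nan, np.nan, "no misclassifications"))
            continue
        vals = col[conclusive]
        uniq = pd.unique(vals.dropna())
        if len(uniq) <= 1:
            rows.append(CovariateEffectRow(name, "not_computable", np.nan, np.nan, "constant covariate"))
            continue
        if len(uniq) == 2:
            pos = vals == uniq.max() if not isinstance(uniq[0], str) else vals == sorted(uniq)[1]
            pos = np.asarray(pos).astype(bool)
            m = mis[conclusive]
            a = int(np.sum(m & pos))
            b = int(np.sum(m & ~pos))
            c = int(np.sum(~m & pos))
            d = int(np.sum(~m & ~pos))
            try:
                oratio, p = fisher_exact(a, b, c, d)
                rows.append(CovariateEffectRow(name, "fisher_exact", oratio, p))
            except ValueError as e:
                rows.append(CovariateEffectRow(name, "not_computable", np.nan, np.nan, str(e)))
        else:
            xm = np.asarray(col[mis], dtype=float)
            xc = np.asarray(col[ok], dtype=float)
            try:
                dstat, p = ks_two_sample(xm[np.isfinite(xm)], xc[np.isfinite(xc)])
                rows.append(CovariateEffectRow(name, "ks_two_sample", dstat, p))
            except ValueError as e:
                rows.append(CovariateEffectRow(name, "not_computable", np.nan, np.nan, str(e)))
    return rows
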