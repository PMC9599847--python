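"""Decision-stump AdaBoost congestion scorer with an inconclusive zone.

Classic discrete AdaBoost over one-feature threshold classifiers
("stumps"): each round t fits the stump minimizing the weighted error
ε_t by exhaustive search over features × thresholds × polarities, receives
weight α_t = ½·ln((1−ε_t)/ε_t), and the sample weights are reweighted by
exp(−α_t·y_i·h_t(x_i)).  Boosting acts both as the feature selector (only
a few tens of features ever enter the stumps) and as the classifier.

The ensemble's weighted vote is mapped affinely onto a 0–1 congestion
score: score = (margin + 1)/2 with margin = Σ α_t h_t(x) / Σ α_t.  The
operating threshold θ is chosen at maximal balanced accuracy, and an
inconclusive (NA) zone of borderline scores around θ is calibrated so
that at most a configured fraction (default 5%) of calibration
measurements are deemed NA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DecisionStump",
    "StumpEnsemble",
    "TrainingTrace",
    "ScoreOutput",
    "fit_stump",
    "train_adaboost",
    "score_measurement",
    "select_operating_point",
    "balanced_accuracy",
    "calibrate_na_zone",
    "classify",
]


@dataclass
class DecisionStump:
    feature_name: str
    feature_index: int
    threshold: float
    polarity: int  # h(x) = polarity if x > threshold else -polarity
    alpha: float = 0.0

    def predict(self, X: np.ndarray) -> np.ndarray:
        x = X[:, self.feature_index]
        return np.where(x > self.threshold, self.polarity, -self.polarity)


@dataclass
class TrainingTrace:
    """Per-round diagnostics of the boosting run.

    ``loss_bound`` is the running Freund–Schapire exponential-loss bound
    ∏_t 2·sqrt(ε_t(1−ε_t)), an upper bound on training misclassification;
    it is non-increasing whenever every accepted round has ε_t < 0.5.
    """

    eps: list[float] = field(default_factory=list)
    alpha: list[float] = field(default_factory=list)
    loss_bound: list[float] = field(default_factory=list)


@dataclass
class StumpEnsemble:
    stumps: list[DecisionStump]
    feature_names: list[str]
    operating_threshold: float | None = None
    na_zone: tuple[float, float] | None = None

    @property
    def n_rounds(self) -> int:
        return len(self.stumps)

    @property
    def selected_features(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.stumps:
            seen.setdefault(s.feature_name)
        return list(seen)

    def margins(self, X: np.ndarray) -> np.ndarray:
        alpha_sum = sum(s.alpha for s in self.stumps)
        votes = np.zeros(X.shape[0])
        for s in self.stumps:
            votes += s.alpha * s.predict(X)
        return votes / alpha_sum if alpha_sum > 0 else votes

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Congestion scores in [0, 1] for a feature matrix."""
        return (self.margins(np.asarray(X, dtype=float)) + 1.0) / 2.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "stumps": [
                    {
                        "feature": s.feature_name,
                        "feature_index": s.feature_index,
                        "threshold": s.threshold,
                        "polarity": s.polarity,
                        "alpha": s.alpha,
                    }
                    for s in self.stumps
                ],
                "feature_names": self.feature_names,
                "theta": self.operating_threshold,
                "na_zone": list(self.na_zone) if self.na_zone else None,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "StumpEnsemble":
        d = json.loads(text)
        return cls(
            stumps=[
                DecisionStump(
                    feature_name=s["feature"],
                    feature_index=s["feature_index"],
                    threshold=s["threshold"],
                    polarity=s["polarity"],
                    alpha=s["alpha"],
                )
                for s in d["stumps"]
            ],
            feature_names=d["feature_names"],
            operating_threshold=d["theta"],
            na_zone=tuple(d["na_zone"]) if d.get("na_zone") else None,
        )


@dataclass
class ScoreOutput:
    measurement_id: str
    score: float
    decision: str  # "case" | "control" | "inconclusive"


def _check_Xyw(X, y, w=None):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    if set(np.unique(y)) - {-1, 1}:
        raise ValueError("labels must be +-1")
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values; impute upstream")
    if w is None:
        w = np.full(len(y), 1.0 / len(y))
    else:
        w = np.asarray(w, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        w = w / w.sum()
    return X, y.astype(float), w


def fit_stump(X, y, w=None, feature_names=None) -> tuple[DecisionStump, float]:
    """Weighted-error-minimizing stump by exhaustive search.

    Candidate thresholds are the midpoints between adjacent sorted unique
    values of each feature; both polarities are tried.  Ties break toward
    the lower feature index, then the lower threshold.  A globally
    constant X has no candidate split and yields a degenerate stump whose
    error is the smaller class-weight sum.
    """
    X, y, w = _check_Xyw(X, y, w)
    n, nfeat = X.shape
    names = feature_names or [f"f{j}" for j in range(nfeat)]
    w_pos = float(np.sum(w[y > 0]))
    w_neg = 1.0 - w_pos
    best = None  # (eps, j, threshold, polarity)
    for j in range(nfeat):
        xj = X[:, j]
        order = np.argsort(xj, kind="stable")
        xs, ys, ws = xj[order], y[order], w[order]
        boundary = np.nonzero(np.diff(xs) > 0)[0]
        if len(boundary) == 0:
            continue
        cp = np.cumsum(ws * (ys > 0))[boundary]  # positive weight at/left of split
        cn = np.cumsum(ws * (ys < 0))[boundary]
        thr = (xs[boundary] + xs[boundary + 1]) / 2.0
        # polarity +1: predict -1 left of the split, +1 right of it
        err_pos = cp + (w_neg - cn)
        err_neg = cn + (w_pos - cp)
        for errs, pol in ((err_pos, +1), (err_neg, -1)):
            i = int(np.argmin(errs))  # first minimum -> lowest threshold
            if best is None or errs[i] < best[0] - 1e-15:
                best = (float(errs[i]), j, float(thr[i]), pol)
    if best is None:  # all features constant
        eps = min(w_pos, w_neg)
        pol = +1 if w_pos >= w_neg else -1
        return DecisionStump(names[0], 0, -np.inf, pol), float(eps)
    eps, j, thr, pol = best
    return DecisionStump(names[j], j, thr, pol), eps


def train_adaboost(
    X,
    y,
    feature_names=None,
    n_rounds: int = 50,
    eps_floor: float = 1e-10,
) -> tuple[StumpEnsemble, TrainingTrace]:
    """Discrete AdaBoost with decision stumps.

    Stops early when no stump beats chance (ε_t ≥ 0.5) or when a stump
    separates perfectly (ε_t capped at ``eps_floor``, the round accepted,
    then training halts).
    """
    X, y, w = _check_Xyw(X, y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    names = feature_names or [f"f{j}" for j in range(X.shape[1])]
    stumps: list[DecisionStump] = []
    trace = TrainingTrace()
    bound = 1.0
    for _ in range(n_rounds):
        stump, eps = fit_stump(X, y, w, names)
        if eps >= 0.5:
            break
        alpha = 0.5 * np.log((1.0 - eps) / max(eps, eps_floor))
        stump.alpha = float(alpha)
        stumps.append(stump)
        bound *= 2.0 * np.sqrt(max(eps, 0.0) * (1.0 - eps))
        trace.eps.append(float(eps))
        trace.alpha.append(float(alpha))
        trace.loss_bound.append(float(bound))
        if eps <= eps_floor:
            break
        h = stump.predict(X)
        w = w * np.exp(-alpha * y * h)
        w = w / w.sum()
    return StumpEnsemble(stumps=stumps, feature_names=list(names)), trace


def score_measurement(model: StumpEnsemble, x, feature_names=None) -> float:
    """Score one feature vector on the 0–1 congestion scale."""
    if isinstance(x, dict):
        try:
            x = np.array([x[name] for name in model.feature_names], dtype=float)
        except KeyError as e:
            raise ValueError(f"missing selected feature {e.args[0]!r}") from None
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != len(model.feature_names):
        raise ValueError("feature vector does not match the model's schema")
    return float(model.scores(x)[0])


def balanced_accuracy(pred_case: np.ndarray, labels: np.ndarray) -> float:
    labels = np.asarray(labels).astype(bool)
    pred_case = np.asarray(pred_case).astype(bool)
    se = np.mean(pred_case[labels]) if labels.any() else np.nan
    sp = np.mean(~pred_case[~labels]) if (~labels).any() else np.nan
    return float((se + sp) / 2.0)


def select_operating_point(scores, labels) -> float:
    """Threshold θ maximizing balanced accuracy (score ≥ θ ⇒ case).

    Candidates are midpoints between adjacent sorted unique scores plus
    {0, 1}; among ties the θ closest to 0.5 wins.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    candidates = np.concatenate(([0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]))
    best_ba, best_theta = -np.inf, 0.5
    for theta in candidates:
        ba = balanced_accuracy(scores >= theta, labels)
        if ba > best_ba + 1e-12 or (
            abs(ba - best_ba) <= 1e-12 and abs(theta - 0.5) < abs(best_theta - 0.5) - 1e-12
        ):
            best_ba, best_theta = ba, theta
    return float(best_theta)


def calibrate_na_zone(
    scores, labels, theta: float, max_na_frac: float = 0.05, grid_step: float = 0.005, max_width: float = 0.25
) -> tuple[float, float]:
    """Calibrate the inconclusive zone (θ−w, θ+w) on a calibration set.

    The half-width w is the largest grid value for which (a) the fraction
    of calibration scores strictly inside the open zone does not exceed
    ``max_na_frac`` and (b) the balanced accuracy on the remaining
    conclusive scores is no worse than with no zone at all (w = 0 always
    qualifies).
    """
    if not (0 <= max_na_frac < 1):
        raise ValueError("max_na_frac must be in [0, 1)")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    base_ba = balanced_accuracy(scores >= theta, labels)
    best_w = 0.0
    for w in np.arange(0.0, max_width + grid_step / 2, grid_step):
        inside = (scores > theta - w) & (scores < theta + w)
        if np.mean(inside) > max_na_frac + 1e-12:
            continue
        keep = ~inside
        if keep.sum() == 0 or labels[keep].all() or not labels[keep].any():
            continue
        ba = balanced_accuracy(scores[keep] >= theta, labels[keep])
        if ba >= base_ba - 1e-12 and w > best_w:
            best_w = float(w)
    return (theta - best_w, theta + best_w)


def classify(model: StumpEnsemble, x, measurement_id: str = "") -> ScoreOutput:
    """Score and call one measurement: case / control / inconclusive.

    The decision is inconclusive iff the score lies strictly inside the
    open NA zone; otherwise score ≥ θ ⇒ case (boundary counts as a call).
    """
    if model.operating_threshold is None or model.na_zone is None:
        raise RuntimeError("model is not calibrated: operating threshold / NA zone unset")
    s = score_measurement(model, x)
    lo, hi = model.na_zone
    if lo < s < hi:
        decision = "inconclusive"
    elif s >= model.operating_threshold:
        decision = "case"
    else:
        decision = "control"
    return ScoreOutput(measurement_id=measurement_id, score=s, decision=decision)
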