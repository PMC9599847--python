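"""Grouped CV, ROC/AUC, diagnostic metrics, bootstrap, Fisher/KS screen."""

import collections

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lungvib as lv
from lungvib.boost import ScoreOutput
from lungvib.config import PipelineConfig
from lungvib.evaluate import (
    CIResult,
    ConfusionCounts,
    bootstrap_ci,
    confusion_counts,
    covariate_effect_table,
    cross_validated_scores,
    diagnostic_metrics,
)


class TestGroupedKfold:
    def test_study_sized_cohort_fold_sizes(self):
        folds = lv.grouped_kfold([f"S{i}" for i in range(227)], k=10, seed=0)
        sizes = sorted(collections.Counter(folds.values()).values())
        assert sizes == [22, 22, 22] + [23] * 7

    def test_one_subject_per_fold(self):
        folds = lv.grouped_kfold([f"S{i}" for i in range(10)], k=10, seed=3)
        assert sorted(collections.Counter(folds.values()).values()) == [1] * 10

    def test_subjects_never_split_across_folds(self):
        ids = [f"S{i % 7}" for i in range(30)]
        folds = lv.grouped_kfold(ids, k=3, seed=1)
        assert len(folds) == 7  # one fold per subject, regardless of repeats

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            lv.grouped_kfold(["a", "b"], k=3)


class TestRocCurve:
    def test_perfect_separation(self):
        _, auc = lv.roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_interleaved_scores_by_pair_enumeration(self):
        _, auc = lv.roc_curve([0.2, 0.4, 0.6, 0.8], [0, 1, 0, 1])
        assert auc == pytest.approx(0.75)

    def test_independent_labels_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(2000)
        labels = rng.random(2000) < 0.5
        _, auc = lv.roc_curve(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_auc_equals_mann_whitney_probability(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            scores = np.round(rng.random(50), 1)  # deliberate ties
            labels = rng.random(50) < 0.4
            if labels.all() or not labels.any():
                continue
            _, auc = lv.roc_curve(scores, labels)
            u = stats.mannwhitneyu(scores[labels], scores[~labels]).statistic
            assert auc == pytest.approx(u / (labels.sum() * (~labels).sum()), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            lv.roc_curve([0.1, 0.9], [1, 1])


def _outputs(decisions):
    return [ScoreOutput(f"m{i}", 0.5, d) for i, d in enumerate(decisions)]


class TestConfusionCounts:
    def test_all_correct(self):
        out = _outputs(["case"] * 5 + ["control"] * 5)
        c = confusion_counts(out, [1] * 5 + [0] * 5)
        assert (c.tp, c.tn, c.fp, c.fn) == (5, 5, 0, 0)

    def test_exclude_policy_sidelines_inconclusives(self):
        out = _outputs(["inconclusive"])
        c = confusion_counts(out, [1], na_policy="exclude")
        assert c.n_inconclusive == 1 and c.tp + c.fn == 0

    def test_count_as_error_policy_charges_the_true_class(self):
        c1 = confusion_counts(_outputs(["inconclusive"]), [1], na_policy="count_as_error")
        assert c1.fn == 1
        c0 = confusion_counts(_outputs(["inconclusive"]), [0], na_policy="count_as_error")
        assert c0.fp == 1


class TestDiagnosticMetrics:
    def test_published_operating_point_identities(self):
        """Se = Sp = 0.91 at 32% prevalence imply PLR ≈ 10, NLR ≈ 0.1,
        PPV ≈ 0.82, NPV ≈ 0.95 by the likelihood-ratio/Bayes identities."""
        rep = diagnostic_metrics(ConfusionCounts(tp=91, fn=9, tn=91, fp=9), 0.32)
        assert rep.plr == pytest.approx(10.0, rel=0.05)
        assert rep.nlr == pytest.approx(0.1, rel=0.05)
        assert rep.ppv_at_p == pytest.approx(0.82, abs=0.01)
        assert rep.npv_at_p == pytest.approx(0.95, abs=0.01)

    def test_perfect_test_markers(self):
        rep = diagnostic_metrics(ConfusionCounts(tp=10, fn=0, tn=10, fp=0), 0.32)
        assert rep.ppv_at_p == 1.0 and rep.npv_at_p == 1.0
        assert rep.nlr == 0.0 and np.isinf(rep.plr)

    def test_direct_arithmetic(self):
        rep = diagnostic_metrics(ConfusionCounts(tp=9, fn=1, tn=8, fp=2))
        assert rep.sensitivity == pytest.approx(0.9)
        assert rep.specificity == pytest.approx(0.8)
        assert rep.plr == pytest.approx(4.5)

    def test_bayes_identity_matches_patient_simulation(self):
        """PPV/NPV at external prevalence agree with a direct simulation of
        10^6 Bernoulli patients within 0.002."""
        se, sp, p = 0.85, 0.9, 0.32
        rep = diagnostic_metrics(
            ConfusionCounts(tp=85, fn=15, tn=90, fp=10), external_prevalence=p
        )
        rng = np.random.default_rng(0)
        disease = rng.random(1_000_000) < p
        pos = np.where(disease, rng.random(1_000_000) < se, rng.random(1_000_000) < 1 - sp)
        assert rep.ppv_at_p == pytest.approx(disease[pos].mean(), abs=0.002)
        assert rep.npv_at_p == pytest.approx((~disease[~pos]).mean(), abs=0.002)

    def test_likelihood_ratio_identities_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            c = ConfusionCounts(*(int(v) for v in rng.integers(1, 50, 4)))
            rep = diagnostic_metrics(c)
            assert rep.plr == pytest.approx(rep.sensitivity / (1 - rep.specificity))
            assert rep.nlr == pytest.approx((1 - rep.sensitivity) / rep.specificity)
            assert (rep.plr >= 1) == (rep.sensitivity >= 1 - rep.specificity)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            diagnostic_metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=5))


class TestBootstrap:
    def test_constant_statistic_degenerate_interval(self):
        ci = bootstrap_ci(lambda idx: 3.14, [f"s{i}" for i in range(20)], n_boot=50, seed=0)
        assert ci.lo == ci.hi == 3.14

    def test_binomial_width_matches_closed_form(self):
        rng = np.random.default_rng(1)
        data = (rng.random(200) < 0.5).astype(float)
        ci = bootstrap_ci(lambda idx: data[idx].mean(), [f"s{i}" for i in range(200)], n_boot=500, seed=2)
        closed = 2 * 1.96 * np.sqrt(0.25 / 200)
        assert (ci.hi - ci.lo) == pytest.approx(closed, rel=0.3)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=50)
        subj = [f"s{i // 2}" for i in range(50)]  # two measurements per subject
        a = bootstrap_ci(lambda idx: data[idx].mean(), subj, n_boot=200, seed=9)
        b = bootstrap_ci(lambda idx: data[idx].mean(), subj, n_boot=200, seed=9)
        assert (a.lo, a.hi) == (b.lo, b.hi)

    def test_mostly_failing_statistic_reported_failed(self):
        ci = bootstrap_ci(lambda idx: np.nan, ["a", "b", "c"], n_boot=50, seed=0)
        assert not ci.ok


class TestFisherExact:
    def test_symmetric_table(self):
        _, p = lv.fisher_exact(1, 1, 1, 1)
        assert p == pytest.approx(1.0)

    def test_enumerated_small_tables(self):
        _, p = lv.fisher_exact(3, 1, 1, 3)
        assert p == pytest.approx(34 / 70)
        _, p = lv.fisher_exact(0, 5, 5, 0)
        assert p == pytest.approx(2 / 252)

    def test_matches_hypergeometric_enumeration_all_small_tables(self):
        """Exhaustive oracle: for every 2x2 table with n ≤ 12, the p-value
        equals the sum over the full hypergeometric support."""
        for n in range(2, 13):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                            continue
                        _, p = lv.fisher_exact(a, b, c, d)
                        # oracle: enumerate tables with fixed margins
                        probs = []
                        for aa in range(0, min(a + b, a + c) + 1):
                            bb, cc = a + b - aa, a + c - aa
                            dd = d - a + aa
                            if min(bb, cc, dd) < 0:
                                continue
                            probs.append(stats.hypergeom.pmf(aa, n, a + c, a + b))
                        probs = np.array(probs)
                        p_obs = stats.hypergeom.pmf(a, n, a + c, a + b)
                        oracle = probs[probs <= p_obs + 1e-12].sum()
                        assert p == pytest.approx(oracle, abs=1e-10), (a, b, c, d)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError):
            lv.fisher_exact(0, 0, 3, 4)


class TestKsTwoSample:
    def test_identical_samples(self):
        d, p = lv.ks_two_sample([1.0, 2, 3], [1.0, 2, 3])
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        d, _ = lv.ks_two_sample([1, 2, 3], [4, 5, 6])
        assert d == 1.0

    def test_interleaved(self):
        d, _ = lv.ks_two_sample([1, 3], [2, 4])
        assert d == 0.5

    def test_d_matches_brute_force_ecdf_scan(self):
        """Oracle: evaluate both ECDFs on the pooled grid for all n ≤ 12."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            x = rng.integers(0, 6, rng.integers(1, 13)).astype(float)
            y = rng.integers(0, 6, rng.integers(1, 13)).astype(float)
            d, _ = lv.ks_two_sample(x, y)
            grid = np.concatenate((x, y))
            oracle = max(
                abs(np.mean(x <= g) - np.mean(y <= g)) for g in grid
            )
            assert d == pytest.approx(oracle, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            lv.ks_two_sample([], [1.0])


class TestCrossValidation:
    def _toy(self, n_subj=30, per_subj=2, informative=True, seed=0):
        rng = np.random.default_rng(seed)
        rows, labs, subs = [], [], []
        for i in range(n_subj):
            lab = i % 2
            base = rng.normal(size=4)
            for j in range(per_subj):
                x = base + rng.normal(0, 0.3, 4)
                if informative:
                    x[0] += 4.0 * lab
                rows.append(x)
                labs.append(lab)
                subs.append(f"s{i}")
        X = pd.DataFrame(rows, columns=list("abcd"))
        return X, np.array(labs), np.array(subs)

    def test_every_measurement_scored_once_and_deterministic(self):
        X, y, s = self._toy()
        cfg = PipelineConfig(k_folds=5, n_boot=10)
        out1, sc1 = cross_validated_scores(X, y, s, cfg, seed=3)
        out2, sc2 = cross_validated_scores(X, y, s, cfg, seed=3)
        assert all(o is not None for o in out1)
        assert np.array_equal(sc1, sc2)
        assert [o.decision for o in out1] == [o.decision for o in out2]

    def test_informative_features_recovered(self):
        X, y, s = self._toy()
        out, sc = cross_validated_scores(X, y, s, PipelineConfig(k_folds=5), seed=1)
        _, auc = lv.roc_curve(sc, y)
        assert auc >= 0.9

    def test_no_leakage_from_grouped_assignment(self):
        """Out-of-fold scores never depend on a subject's own data: folds
        keep a subject's repeats together, and duplicating a held-out
        subject into training demonstrably changes its score (so the
        grouped split is what protects it)."""
        X, y, s = self._toy(seed=5)
        cfg = PipelineConfig(k_folds=5)
        fold_of = lv.grouped_kfold(s, k=5, seed=cfg.seed)
        folds = np.array([fold_of[x] for x in s])
        # same-subject measurements share a fold
        for subj in set(s.tolist()):
            assert len(set(folds[s == subj])) == 1
        # leakage counterfactual: train fold-0 model with/without test rows
        from lungvib.boost import train_adaboost
        from lungvib.features import impute_with_medians

        test = folds == 0
        Xa = X.to_numpy()
        ysym = np.where(y.astype(bool), 1.0, -1.0)
        Xtr, med = impute_with_medians(Xa[~test])
        clean, _ = train_adaboost(Xtr, ysym[~test], list(X.columns))
        leaky, _ = train_adaboost(
            np.vstack([Xtr, Xa[test]]), np.concatenate([ysym[~test], ysym[test]]), list(X.columns)
        )
        assert not np.allclose(clean.scores(Xa[test]), leaky.scores(Xa[test]))


class TestCovariateScreen:
    def _outputs_and_labels(self, n=200, err=0.15, seed=0):
        rng = np.random.default_rng(seed)
        labels = rng.random(n) < 0.5
        wrong = rng.random(n) < err
        decisions = np.where(labels ^ wrong, "case", "control")
        outputs = [ScoreOutput(f"m{i}", 0.5, d) for i, d in enumerate(decisions)]
        return outputs, labels, wrong, rng

    def test_independent_covariates_are_null(self):
        outputs, labels, _, rng = self._outputs_and_labels()
        cov = pd.DataFrame(
            {f"bin{i}": (rng.random(200) < 0.4).astype(int) for i in range(5)}
            | {f"cont{i}": rng.normal(size=200) for i in range(5)}
        )
        rows = covariate_effect_table(outputs, labels, cov)
        pvals = np.array([r.p_value for r in rows])
        assert np.mean(pvals < 0.05) <= 0.10

    def test_covariate_equal_to_error_indicator_is_detected(self):
        outputs, labels, wrong, _ = self._outputs_and_labels()
        rows = covariate_effect_table(outputs, labels, pd.DataFrame({"err": wrong.astype(int)}))
        assert rows[0].test == "fisher_exact"
        assert rows[0].p_value < 1e-10

    def test_constant_covariate_not_computable(self):
        outputs, labels, _, _ = self._outputs_and_labels()
        rows = covariate_effect_table(outputs, labels, pd.DataFrame({"c": np.ones(200)}))
        assert rows[0].test == "not_computable"

    def test_no_misclassifications_reported(self):
        labels = np.array([1, 0, 1, 0], dtype=bool)
        outputs = [ScoreOutput(f"m{i}", 0.5, "case" if l else "control") for i, l in enumerate(labels)]
        rows = covariate_effect_table(outputs, labels, pd.DataFrame({"x": [1.0, 2, 3, 4]}))
        assert rows[0].test == "not_computable"
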