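"""Metric suite against brute-force / resampling oracles and printed-count identities."""

import numpy as np
import pytest

from fedcmc.evaluation import (
    confusion_metrics,
    dca_curve,
    delong_ci,
    delong_test,
    fairness_report,
    make_report,
    nri_idi,
    pca_projection,
    pr_auc,
    roc_auc,
    youden_threshold,
)


# --- independent oracles ----------------------------------------------------

def _auc_pairwise(scores, labels):
    """Mann-Whitney by direct pair counting."""
    s = np.asarray(scores)
    y = np.asarray(labels)
    pos, neg = s[y == 1], s[y == 0]
    diff = np.subtract.outer(pos, neg)  # all (positive, negative) pairs
    wins = (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return wins / (len(pos) * len(neg))


def _youden_brute(scores, labels):
    s, y = np.asarray(scores), np.asarray(labels)
    best = (-np.inf, None)
    for t in sorted(np.unique(s)):
        pred = s >= t
        j = pred[y == 1].mean() + (~pred)[y == 0].mean() - 1.0
        if j > best[0] + 1e-15:
            best = (j, t)
    return best[1], best[0]


class TestRocAuc:
    def test_matches_pairwise_oracle_on_random_toys(self, rng):
        for _ in range(100):
            n = rng.integers(6, 40)
            y = np.r_[np.ones(3, int), np.zeros(3, int), rng.integers(0, 2, n - 6)]
            s = np.round(rng.random(n), 2)  # rounding forces ties
            assert roc_auc(s, y) == pytest.approx(_auc_pairwise(s, y), abs=1e-12)

    def test_known_values(self):
        assert roc_auc([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == pytest.approx(0.75)
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0]) == 0.5

    def test_invariant_under_monotone_transform(self, rng):
        s = rng.random(60)
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        assert roc_auc(np.exp(3 * s) - 1, y) == pytest.approx(roc_auc(s, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestDeLong:
    def test_ci_brackets_auc_and_orders(self, rng):
        s = rng.normal(0, 1, 80) + np.r_[np.ones(40), np.zeros(40)]
        y = np.r_[np.ones(40, int), np.zeros(40, int)]
        auc, lo, hi = delong_ci(s, y)
        assert lo <= auc <= hi
        assert auc == pytest.approx(roc_auc(s, y), abs=1e-12)

    def test_variance_against_bootstrap(self, rng):
        """DeLong variance within 25% of a 2000-rep bootstrap on an AUC~0.8 toy."""
        n = 60
        y = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        s = rng.normal(0, 1, n) + 1.2 * y
        auc, lo, hi = delong_ci(s, y, level=0.95)
        var_delong = ((hi - lo) / (2 * 1.959963984540054)) ** 2
        boots = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            yy, ss = y[idx], s[idx]
            if yy.min() == yy.max():
                continue
            boots.append(_auc_pairwise(ss, yy))
        var_boot = np.var(boots, ddof=1)
        assert abs(var_delong - var_boot) / var_boot < 0.25

    def test_ci_narrows_with_sample_size(self, rng):
        widths = []
        for n in (30, 300):
            y = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
            s = rng.normal(0, 1, n) + y
            _, lo, hi = delong_ci(s, y)
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_perfect_separation_collapses_ci(self):
        y = np.array([1, 1, 0, 0])
        with pytest.warns(UserWarning):
            auc, lo, hi = delong_ci([0.9, 0.8, 0.2, 0.1], y)
        assert auc == lo == hi == 1.0

    def test_identical_scores_give_p_one_and_symmetry(self, rng):
        s = rng.random(40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        assert delong_test(s, s, y) == 1.0
        b = rng.random(40)
        assert delong_test(s, b, y) == pytest.approx(delong_test(b, s, y), abs=1e-12)

    def test_agrees_with_permutation_oracle_on_clear_difference(self, rng):
        """A strictly better model should be flagged by both tests at alpha=0.05."""
        n = 100
        y = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        good = 2.0 * y + rng.normal(0, 1, n)
        bad = rng.normal(0, 1, n)
        p_delong = delong_test(good, bad, y)
        # permutation: swap each sample's pair of scores at random
        diff_obs = abs(_auc_pairwise(good, y) - _auc_pairwise(bad, y))
        count = 0
        reps = 5000
        for _ in range(reps):
            swap = rng.random(n) < 0.5
            a = np.where(swap, bad, good)
            b = np.where(swap, good, bad)
            if abs(_auc_pairwise(a, y) - _auc_pairwise(b, y)) >= diff_obs - 1e-12:
                count += 1
        p_perm = count / reps
        assert (p_delong < 0.05) and (p_perm < 0.05)


class TestYouden:
    def test_hand_example(self):
        t, j = youden_threshold([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert (t, j) == (0.8, pytest.approx(1.0))

    def test_all_tied_scores(self):
        t, j = youden_threshold([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert j == pytest.approx(0.0)

    def test_matches_brute_force_on_random_toys(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 30))
            y = np.r_[1, 0, rng.integers(0, 2, n - 2)]
            s = np.round(rng.random(n), 1)
            t, j = youden_threshold(s, y)
            t_b, j_b = _youden_brute(s, y)
            assert j == pytest.approx(j_b, abs=1e-12)
            assert t == pytest.approx(t_b, abs=1e-12)


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "tp,fn,tn,fp,acc,f1",
        [
            (140, 35, 16, 9, 156 / 200, 280 / 324),  # large-center test split
            (97, 13, 6, 2, 103 / 118, 194 / 209),  # mid-size center
            (36, 1, 5, 1, 41 / 43, 72 / 74),  # small center
        ],
    )
    def test_printed_count_identities(self, tp, fn, tn, fp, acc, f1):
        """Accuracy and F1 recomputed from confusion counts match the fractions."""
        scores = np.r_[np.ones(tp), np.zeros(fn), np.zeros(tn), np.ones(fp)]
        labels = np.r_[np.ones(tp + fn, dtype=int), np.zeros(tn + fp, dtype=int)]
        m = confusion_metrics(scores, labels, threshold=0.5)
        assert (m["TP"], m["FN"], m["TN"], m["FP"]) == (tp, fn, tn, fp)
        assert m["accuracy"] == pytest.approx(acc, abs=1e-12)
        assert m["f1"] == pytest.approx(f1, abs=1e-12)
        assert m["sensitivity"] == pytest.approx(tp / (tp + fn), abs=1e-12)
        assert m["specificity"] == pytest.approx(tn / (tn + fp), abs=1e-12)

    def test_threshold_below_min_score(self, rng):
        s = rng.uniform(0.2, 0.9, 30)
        y = np.r_[np.ones(20, int), np.zeros(10, int)]
        m = confusion_metrics(s, y, threshold=0.0)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0

    def test_f1_consistent_with_precision_recall(self, rng):
        s = rng.random(50)
        y = np.r_[np.ones(25, int), np.zeros(25, int)]
        m = confusion_metrics(s, y, threshold=0.5)
        p, r = m["precision"], m["sensitivity"]
        assert m["f1"] == pytest.approx(2 * p * r / (p + r), abs=1e-12)


class TestPrAuc:
    def test_perfect_separation(self):
        assert pr_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_uninformative_scores_near_prevalence(self, rng):
        n = 2000
        y = (rng.random(n) < 0.3).astype(int)
        s = rng.random(n)
        assert pr_auc(s, y) == pytest.approx(y.mean(), abs=0.05)

    def test_matches_step_enumeration_on_toy(self):
        """Step-wise AP on a 6-sample toy, by hand over descending cutpoints."""
        s = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        y = np.array([1, 0, 1, 1, 0, 0])
        # recall steps at each positive: (1/3)*1/1? No: AP = sum dR * precision
        # positives at ranks 1,3,4 -> precisions 1/1, 2/3, 3/4; each dR = 1/3
        expected = (1.0 + 2 / 3 + 3 / 4) / 3
        assert pr_auc(s, y) == pytest.approx(expected, abs=1e-12)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_auc([0.1, 0.2], [0, 0])


class TestNriIdi:
    def test_identical_models_are_zero(self, rng):
        s = rng.random(30)
        y = np.r_[np.ones(15, int), np.zeros(15, int)]
        nri, idi = nri_idi(s, s, y, threshold=0.5)
        assert nri == 0.0 and idi == 0.0

    def test_hand_reclassification_example(self):
        # 2 events, 2 nonevents; one event reclassified up, nothing else moves
        y = np.array([1, 1, 0, 0])
        old = np.array([0.4, 0.9, 0.2, 0.1])
        new = np.array([0.6, 0.9, 0.2, 0.1])
        nri, idi = nri_idi(old, new, y, threshold=0.5)
        assert nri == pytest.approx(0.5)

    def test_nri_bounded(self, rng):
        for _ in range(20):
            y = np.r_[np.ones(10, int), np.zeros(10, int)]
            nri, _ = nri_idi(rng.random(20), rng.random(20), y, 0.5)
            assert -2.0 <= nri <= 2.0


class TestDca:
    def test_treat_none_is_zero_and_hand_value(self):
        # n=10, threshold 0.2: TP=3, FP=1 -> 0.3 - 0.1*0.25 = 0.275
        s = np.r_[np.full(3, 0.9), np.full(1, 0.9), np.full(2, 0.1), np.full(4, 0.1)]
        y = np.r_[1, 1, 1, 0, 1, 1, 0, 0, 0, 0].astype(int)
        out = dca_curve(s, y, [0.2])
        assert out["treat_none"][0] == 0.0
        assert out["net_benefit"][0] == pytest.approx(0.3 - 0.1 * 0.25, abs=1e-12)

    def test_perfect_classifier_reaches_prevalence(self, rng):
        y = np.r_[np.ones(30, int), np.zeros(70, int)]
        s = y * 0.8 + 0.1  # positives 0.9, negatives 0.1
        grid = np.array([0.2, 0.5, 0.8])
        out = dca_curve(s, y, grid)
        assert np.allclose(out["net_benefit"], y.mean())

    def test_net_benefit_bounded_by_prevalence(self, rng):
        s = rng.random(200)
        y = (rng.random(200) < 0.4).astype(int)
        out = dca_curve(s, y, np.linspace(0.05, 0.95, 19))
        assert np.all(out["net_benefit"] <= y.mean() + 1e-12)

    def test_grid_at_one_rejected(self):
        with pytest.raises(ValueError):
            dca_curve([0.5], [1], [1.0])


class TestFairnessReport:
    def test_identical_rows_zero(self):
        table = {"fedcmc": {"A": 0.8, "B": 0.7}, "fedavg": {"A": 0.8, "B": 0.7}}
        rep = fairness_report(table)
        assert rep.performance_improvement_pct == pytest.approx(0.0)
        assert rep.fairness_improvement_pct == pytest.approx(0.0)

    def test_uniform_gain_and_skipped_sigma(self):
        table = {
            "fedcmc": {"A": 0.9, "B": 0.9, "C": 0.9},
            "fedavg": {"A": 0.8, "B": 0.8, "C": 0.8},
        }
        with pytest.warns(UserWarning):
            rep = fairness_report(table)
        assert rep.performance_improvement_pct == pytest.approx(12.5)
        assert np.isnan(rep.fairness_improvement_pct)
        assert rep.skipped_baselines == ["fedavg"]

    def test_halved_spread_is_fifty_percent(self):
        # ours spans exactly half the baseline's spread -> sigma ratio 1/2
        base = {"A": 0.75, "B": 0.80, "C": 0.85}
        ours = {"A": 0.825, "B": 0.85, "C": 0.875}
        rep = fairness_report({"fedcmc": ours, "fedavg": base})
        assert rep.fairness_improvement_pct == pytest.approx(50.0)


class TestPca:
    def test_shape_and_variance_order(self, rng):
        X = rng.normal(0, 1, (50, 6)) * np.array([5, 3, 1, 1, 1, 1])
        Z = pca_projection(X, out_dim=2)
        assert Z.shape == (50, 2)
        assert Z[:, 0].var() >= Z[:, 1].var()

    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(0, 1, (10, 4))
        Z = pca_projection(X, out_dim=2)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        top = evecs[:, np.argsort(evals)[::-1][:2]]
        Z_oracle = Xc @ top
        for j in range(2):  # eigenvectors defined up to sign
            assert min(
                np.abs(Z[:, j] - Z_oracle[:, j]).max(),
                np.abs(Z[:, j] + Z_oracle[:, j]).max(),
            ) < 1e-8

    def test_constant_columns_dropped_with_warning(self, rng):
        X = np.hstack([rng.normal(0, 1, (20, 3)), np.ones((20, 1))])
        with pytest.warns(UserWarning):
            Z = pca_projection(X, out_dim=2)
        assert Z.shape == (20, 2)


def test_make_report_internally_consistent(rng):
    y = np.r_[np.ones(60, int), np.zeros(30, int)]
    s = np.clip(rng.normal(0.6, 0.2, 90) + 0.25 * y - 0.125, 0.01, 0.99)
    rep = make_report("X", s, y)
    c = rep.counts
    n = sum(c.values())
    assert n == 90
    assert rep.accuracy == pytest.approx((c["TP"] + c["TN"]) / n, abs=1e-12)
    assert rep.ci_low <= rep.auc <= rep.ci_high
    # the reported threshold is the Youden optimum
    t, _ = youden_threshold(s, y)
    assert rep.threshold == t
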