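"""Balanced split arithmetic, confusion metrics and interaction aggregation."""

import numpy as np
import pandas as pd
import pytest

from beanprint.dataset import LabelScheme
from beanprint.evaluate import (
    SplitError,
    aggregate_interactions,
    confusion_matrix,
    evaluate_predictions,
    make_balanced_splits,
    sensitivity_specificity,
)

from conftest import meta_only_dataset


def scheme_for(ds):
    return LabelScheme.from_metadata(ds, level="country-set")


class TestBalancedSplits:
    def test_yemen_vs_other_design_arithmetic(self):
        # 124 + 97 samples x 4 replicates; 36 + 9 test samples
        ds = meta_only_dataset({"Other": 97, "Yemen": 124})
        scheme = LabelScheme.from_metadata(
            ds, level="country-set", classes=["Yemen", "Other"]
        )
        plans = make_balanced_splits(
            ds, scheme, {"Yemen": 36, "Other": 9}, n_interactions=3, seed=5
        )
        sample_of = ds.meta["sample_id"].to_numpy()
        y = ds.meta["country"].to_numpy()
        for plan in plans:
            train, cv, test = plan.counts()
            assert (train, cv, test) == (564, 140, 180)
            for cls, n_tr, n_cv in (("Yemen", 282, 70), ("Other", 282, 70)):
                assert np.sum(y[plan.train_idx] == cls) == n_tr
                assert np.sum(y[plan.cv_idx] == cls) == n_cv
            # sample grouping: test samples contribute all 4 replicates
            test_samples = set(sample_of[plan.test_idx])
            assert test_samples == set(plan.test_samples)
            assert not test_samples & set(sample_of[plan.train_idx])
            assert not test_samples & set(sample_of[plan.cv_idx])

    def test_small_80_20_rounding(self):
        # 5 samples x 2 replicates per class, 1 test sample -> 8 remain -> 6/2
        ds = meta_only_dataset({"A": 5, "B": 5}, n_replicates=2)
        plans = make_balanced_splits(ds, scheme_for(ds), {"A": 1, "B": 1}, seed=0)
        train, cv, test = plans[0].counts()
        assert (train, cv, test) == (12, 4, 4)

    def test_same_seed_reproduces_plans(self):
        ds = meta_only_dataset({"A": 8, "B": 6})
        a = make_balanced_splits(ds, scheme_for(ds), {"A": 2, "B": 1}, seed=3)
        b = make_balanced_splits(ds, scheme_for(ds), {"A": 2, "B": 1}, seed=3)
        for pa, pb in zip(a, b):
            assert pa.test_samples == pb.test_samples
            np.testing.assert_array_equal(pa.train_idx, pb.train_idx)
            np.testing.assert_array_equal(pa.cv_idx, pb.cv_idx)

    def test_different_seeds_vary(self):
        ds = meta_only_dataset({"A": 20, "B": 20})
        draws = {
            tuple(
                make_balanced_splits(ds, scheme_for(ds), {"A": 5, "B": 5}, seed=s)[
                    0
                ].test_samples
            )
            for s in range(20)
        }
        assert len(draws) > 1

    def test_partition_disjointness(self):
        ds = meta_only_dataset({"A": 10, "B": 7, "C": 9})
        plans = make_balanced_splits(
            ds, scheme_for(ds), {"A": 2, "B": 1, "C": 2}, seed=9
        )
        for plan in plans:
            used = np.concatenate([plan.train_idx, plan.cv_idx, plan.test_idx])
            assert len(used) == len(set(used.tolist()))

    def test_infeasible_design_names_limiting_class(self):
        ds = meta_only_dataset({"A": 3, "B": 10})
        with pytest.raises(SplitError, match="'A'"):
            make_balanced_splits(ds, scheme_for(ds), {"A": 2, "B": 1}, seed=0)


class TestConfusionMatrix:
    def test_diagonal_when_perfect(self):
        y = np.array(list("AABBBC"), dtype=object)
        cm = confusion_matrix(y, y, ["A", "B", "C"])
        np.testing.assert_array_equal(cm, np.diag([2, 3, 1]))

    def test_two_class_example(self):
        cm = confusion_matrix(["A", "A", "B"], ["A", "B", "B"], ["A", "B"])
        np.testing.assert_array_equal(cm, [[1, 1], [0, 1]])

    def test_random_labels_match_pair_counting(self):
        rng = np.random.default_rng(21)
        classes = ["X", "Y", "Z"]
        yt = rng.choice(classes, 100)
        yp = rng.choice(classes, 100)
        cm = confusion_matrix(yt, yp, classes)
        for i, a in enumerate(classes):
            for j, b in enumerate(classes):
                assert cm[i, j] == int(np.sum((yt == a) & (yp == b)))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="outside declared"):
            confusion_matrix(["A"], ["Q"], ["A", "B"])


class TestSensitivitySpecificity:
    def test_perfect_three_class(self):
        rep = sensitivity_specificity(np.diag([5, 7, 3]), ["A", "B", "C"])
        assert rep.accuracy_pct == 100.0
        np.testing.assert_allclose(rep.sensitivity_pct, 100.0)
        np.testing.assert_allclose(rep.specificity_pct, 100.0)

    def test_binary_counts_from_balanced_design(self):
        # TP=273 FN=9 / FP=0 TN=282 with Yemen as the positive class
        cm = np.array([[273, 9], [0, 282]])
        rep = sensitivity_specificity(cm, ["Yemen", "Other"], positive_class="Yemen")
        assert rep.summary_sensitivity_pct == pytest.approx(96.81, abs=0.005)
        assert rep.summary_specificity_pct == pytest.approx(100.0)
        assert rep.accuracy_pct == pytest.approx(98.40, abs=0.005)

    def test_three_class_one_vs_rest_counts(self):
        cm = np.array([[8, 1, 1], [0, 9, 1], [2, 0, 8]])
        rep = sensitivity_specificity(cm, ["A", "B", "C"])
        np.testing.assert_allclose(rep.sensitivity_pct, [80.0, 90.0, 80.0])
        # brute-force TP/FN/FP/TN enumeration
        total = cm.sum()
        for i in range(3):
            tp = cm[i, i]
            fn = cm[i].sum() - tp
            fp = cm[:, i].sum() - tp
            tn = total - tp - fn - fp
            assert rep.specificity_pct[i] == pytest.approx(tn / (tn + fp) * 100)

    def test_tp_sum_equals_trace_and_balanced_accuracy_identity(self):
        rng = np.random.default_rng(33)
        cm = rng.integers(0, 20, size=(4, 4))
        cm += np.diag(np.full(4, 30))  # balanced-ish rows
        rep = sensitivity_specificity(cm, list("ABCD"))
        tps = np.diag(cm)
        assert tps.sum() == np.trace(cm)
        # with equal row totals, accuracy equals the mean per-class sensitivity
        cm_bal = np.array([[8, 2, 0], [1, 7, 2], [3, 0, 7]])
        rep_bal = sensitivity_specificity(cm_bal, list("ABC"))
        assert rep_bal.accuracy_pct == pytest.approx(
            np.mean(rep_bal.sensitivity_pct)
        )

    def test_empty_class_row_warns_and_excluded_from_macro(self):
        cm = np.array([[5, 0, 0], [0, 0, 0], [0, 1, 4]])
        with pytest.warns(UserWarning, match="no true spectra"):
            rep = sensitivity_specificity(cm, list("ABC"))
        assert np.isnan(rep.sensitivity_pct[1])
        assert rep.macro_sensitivity_pct == pytest.approx(
            np.mean([rep.sensitivity_pct[0], rep.sensitivity_pct[2]])
        )


class TestAggregation:
    def make_report(self, acc_shift=0.0):
        yt = np.array(["A"] * 10 + ["B"] * 10, dtype=object)
        yp = yt.copy()
        return evaluate_predictions(yt, yp, ["A", "B"])

    def test_identical_reports_have_zero_sd(self):
        reps = [self.make_report() for _ in range(3)]
        table = aggregate_interactions(reps)
        assert (table["sd"] == 0).all()

    def test_mean_sd_match_two_pass_oracle_and_render_one_decimal(self):
        cms = [
            np.array([[123, 2], [0, 125]]),
            np.array([[124, 1], [0, 125]]),
            np.array([[124, 1], [1, 124]]),
        ]
        reps = [sensitivity_specificity(c, ["A", "B"], "A") for c in cms]
        table = aggregate_interactions(reps).set_index("metric")
        accs = np.array([r.accuracy_pct for r in reps])
        mean = accs.sum() / 3
        sd = np.sqrt(((accs - mean) ** 2).sum() / 2)  # two-pass, n-1
        row = table.loc["accuracy_pct"]
        assert row["mean"] == pytest.approx(mean)
        assert row["sd"] == pytest.approx(sd)
        assert row["display"] == f"{mean:.1f} ± {sd:.1f}"

    def test_mismatched_class_sets_rejected(self):
        a = evaluate_predictions(["A", "B"], ["A", "B"], ["A", "B"])
        b = evaluate_predictions(["A", "C"], ["A", "C"], ["A", "C"])
        with pytest.raises(ValueError, match="mismatched"):
            aggregate_interactions([a, a, b])
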