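"""Confusion matrices, one-vs-rest metrics, macro aggregation and the
two-way ANOVA with replication (checked against a from-scratch
sums-of-squares decomposition)."""

import numpy as np
import pytest
from scipy import stats as sstats

from respaug.classification_eval import (
    AnovaResult,
    anova_two_way,
    confusion,
    critical_f,
    macro_report,
    per_class_metrics,
)
from respaug.io import CLASS_LABELS


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        labels = list(CLASS_LABELS) * 3
        cm = confusion(labels, labels)
        assert np.all(cm == 3 * np.eye(7, dtype=int))

    def test_known_errors_off_diagonal(self):
        true = ["COPD", "COPD", "URTI", "URTI", "LRTI", "LRTI"]
        pred = ["COPD", "URTI", "URTI", "URTI", "LRTI", "COPD"]
        cm = confusion(true, pred)
        assert cm.sum() == 6
        assert cm.sum() - np.trace(cm) == 2

    def test_matches_pairwise_tally_oracle(self):
        rng = np.random.default_rng(0)
        true = [CLASS_LABELS[i] for i in rng.integers(0, 7, 60)]
        pred = [CLASS_LABELS[i] for i in rng.integers(0, 7, 60)]
        cm = confusion(true, pred)
        for i, a in enumerate(CLASS_LABELS):
            for j, b in enumerate(CLASS_LABELS):
                assert cm[i, j] == sum(
                    t == a and p == b for t, p in zip(true, pred)
                )

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion(["COPD"], ["Flu"])

    def test_row_sums_are_per_class_counts(self):
        true = ["COPD"] * 4 + ["URTI"] * 2
        pred = ["COPD", "URTI", "COPD", "LRTI", "URTI", "COPD"]
        cm = confusion(true, pred)
        assert cm[0].sum() == 4 and cm[2].sum() == 2


class TestPerClassMetrics:
    def test_perfect_classifier_all_ones(self):
        labels = list(CLASS_LABELS) * 2
        m = per_class_metrics(confusion(labels, labels))
        for c in CLASS_LABELS:
            assert m.precision[c] == m.recall[c] == 1.0
            assert m.specificity[c] == m.f1[c] == 1.0

    def test_binary_toy_matrix_hand_arithmetic(self):
        # class A: TP=8, FN=2, FP=1, TN=9
        cm = np.array([[8, 2], [1, 9]])
        m = per_class_metrics(cm, class_labels=("A", "B"))
        assert m.precision["A"] == pytest.approx(8 / 9)
        assert m.recall["A"] == pytest.approx(0.8)
        assert m.specificity["A"] == pytest.approx(0.9)
        assert m.f1["A"] == pytest.approx(2 * (8 / 9) * 0.8 / (8 / 9 + 0.8))
        assert m.f1["A"] == pytest.approx(0.842, abs=5e-4)

    def test_absent_class_all_zero_with_flag(self):
        cm = np.zeros((3, 3), dtype=int)
        cm[0, 0] = cm[1, 1] = 5  # class "C" never present nor predicted
        m = per_class_metrics(cm, class_labels=("A", "B", "C"))
        assert m.precision["C"] == m.recall["C"] == m.f1["C"] == 0.0
        assert m.degenerate["C"]

    def test_f1_is_harmonic_mean(self):
        rng = np.random.default_rng(1)
        true = [CLASS_LABELS[i] for i in rng.integers(0, 7, 100)]
        pred = [CLASS_LABELS[i] for i in rng.integers(0, 7, 100)]
        m = per_class_metrics(confusion(true, pred))
        for c in CLASS_LABELS:
            p, r = m.precision[c], m.recall[c]
            if p > 0 and r > 0:
                assert m.f1[c] == pytest.approx(2 / (1 / p + 1 / r))

    def test_one_vs_rest_counts_conserved(self):
        rng = np.random.default_rng(2)
        true = [CLASS_LABELS[i] for i in rng.integers(0, 7, 50)]
        pred = [CLASS_LABELS[i] for i in rng.integers(0, 7, 50)]
        cm = confusion(true, pred)
        assert sum(cm[i, i] for i in range(7)) == np.trace(cm)


class TestMacroReport:
    def test_single_value(self):
        assert macro_report([0.7]) == (0.7, 0.0)

    def test_two_point_hand_arithmetic(self):
        mean, std = macro_report([0.0, 1.0])
        assert mean == 0.5 and std == 0.5

    def test_matches_flat_loop_oracle(self):
        rng = np.random.default_rng(0)
        values = rng.random((7, 3))
        mean, std = macro_report(values)
        flat = [v for row in values for v in row]
        assert mean == pytest.approx(sum(flat) / len(flat))
        assert std == pytest.approx(
            np.sqrt(sum((v - mean) ** 2 for v in flat) / len(flat))
        )


def anova_ss_oracle(table):
    """From-scratch sums-of-squares decomposition for a balanced two-way
    design with replication; returns the row-factor F and p."""
    a, b, r = table.shape
    grand = table.mean()
    row_means = table.mean(axis=(1, 2))
    col_means = table.mean(axis=(0, 2))
    cell_means = table.mean(axis=2)
    ss_rows = b * r * ((row_means - grand) ** 2).sum()
    ss_cols = a * r * ((col_means - grand) ** 2).sum()
    ss_inter = r * ((cell_means - row_means[:, None]
                     - col_means[None, :] + grand) ** 2).sum()
    ss_error = ((table - cell_means[:, :, None]) ** 2).sum()
    df_rows, df_error = a - 1, a * b * (r - 1)
    f = (ss_rows / df_rows) / (ss_error / df_error)
    p = sstats.f.sf(f, df_rows, df_error)
    return f, p


class TestAnova:
    def test_critical_f_3_400(self):
        assert round(critical_f(3, 400), 2) == 2.63

    def test_matches_sums_of_squares_oracle_on_toy_design(self):
        rng = np.random.default_rng(0)
        table = rng.normal(size=(2, 2, 2)) + np.array(
            [[[0.0]], [[1.0]]]
        )  # real row effect
        res = anova_two_way(table)
        f, p = anova_ss_oracle(table)
        assert res.f_ratio == pytest.approx(f, rel=1e-8)
        assert res.p_value == pytest.approx(p, rel=1e-8)
        assert res.df_factor == 1 and res.df_error == 4

    def test_matches_oracle_on_experiment_sized_design(self):
        rng = np.random.default_rng(3)
        table = rng.normal(size=(4, 5, 21))
        res = anova_two_way(table)
        f, p = anova_ss_oracle(table)
        assert res.f_ratio == pytest.approx(f, rel=1e-8)
        assert res.p_value == pytest.approx(p, rel=1e-8)
        assert res.df_error == 400
        assert res.critical_f == pytest.approx(critical_f(3, 400))

    def test_type_one_error_rate_near_alpha(self):
        """Under the null (equal cell means), the row-factor p-value is
        uniform: rejections at 0.05 occur in ~5% of simulations."""
        rng = np.random.default_rng(12)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            table = rng.normal(size=(4, 5, 4))
            f, p = anova_ss_oracle(table)
            rejections += p < 0.05
        assert abs(rejections / n_sim - 0.05) <= 0.02

    def test_unbalanced_design_rejected(self):
        with pytest.raises(ValueError):
            anova_two_way(np.zeros((2, 2)))

    def test_zero_within_cell_variance_flagged(self):
        table = np.tile(np.arange(4.0)[:, None, None], (1, 3, 2))
        res = anova_two_way(table)
        assert isinstance(res, AnovaResult)
        assert res.degenerate
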