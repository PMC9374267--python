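"""Per-class and macro classification metrics, trial aggregation, and the
two-way ANOVA with replication comparing training sets x classifiers.

Metrics follow the one-vs-rest reduction of the 7x7 confusion matrix:
precision TP/(TP+FP), recall (sensitivity) TP/(TP+FN), specificity
TN/(TN+FP), F1 = 2PR/(P+R); any zero-denominator metric is defined as 0
and flagged.  Macro statistics are unweighted mean ± population std over
(class x trial) values.

The ANOVA treats the training set as the row factor, the classifier as the
column factor, and each per-class metric value per trial as a replicate
(7 classes x 3 trials = 21 per cell in the standard design, giving error
df 4*5*20 = 400).  The reported F ratio, critical value and p-value are
those of the training-set factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .io import CLASS_LABELS


def confusion(true_labels, predicted_labels,
              class_labels=CLASS_LABELS) -> np.ndarray:
    """Confusion matrix with rows = true class, columns = predicted class."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    index = {c: i for i, c in enumerate(class_labels)}
    cm = np.zeros((len(class_labels), len(class_labels)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"unknown label in ({t!r}, {p!r})")
        cm[index[t], index[p]] += 1
    return cm


@dataclass
class ClassMetrics:
    precision: dict[str, float]
    recall: dict[str, float]
    specificity: dict[str, float]
    f1: dict[str, float]
    degenerate: dict[str, bool]  # any zero-denominator metric for the class

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"precision": self.precision, "recall": self.recall,
             "specificity": self.specificity, "f1": self.f1}
        )


def per_class_metrics(cm: np.ndarray,
                      class_labels=CLASS_LABELS) -> ClassMetrics:
    """One-vs-rest precision/recall/specificity/F1 per class."""
    cm = np.asarray(cm)
    n = cm.sum()
    precision, recall, specificity, f1, degenerate = {}, {}, {}, {}, {}
    for i, label in enumerate(class_labels):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        tn = n - tp - fp - fn
        flag = False

        def ratio(num, den):
            nonlocal flag
            if den == 0:
                flag = True
                return 0.0
            return float(num / den)

        p = ratio(tp, tp + fp)
        r = ratio(tp, tp + fn)
        s = ratio(tn, tn + fp)
        f = ratio(2 * p * r, p + r) if (p + r) > 0 else 0.0
        if (p + r) == 0:
            flag = True
        precision[label], recall[label] = p, r
        specificity[label], f1[label] = s, f
        degenerate[label] = flag
    return ClassMetrics(precision, recall, specificity, f1, degenerate)


def macro_report(metric_values: np.ndarray) -> tuple[float, float]:
    """Unweighted mean and population (ddof=0) std over a flat collection of
    per-class, per-trial metric values."""
    values = np.asarray(metric_values, dtype=float).ravel()
    return float(values.mean()), float(values.std(ddof=0))


@dataclass
class AnovaResult:
    f_ratio: float
    critical_f: float
    p_value: float
    df_factor: int
    df_error: int
    degenerate: bool  # zero within-cell variance


def critical_f(df_factor: int, df_error: int, alpha: float = 0.05) -> float:
    """Upper critical value of the F distribution at significance alpha."""
    return float(sstats.f.ppf(1.0 - alpha, df_factor, df_error))


def anova_two_way(table: np.ndarray, alpha: float = 0.05) -> AnovaResult:
    """Two-way ANOVA with replication on a balanced design.

    ``table`` has shape (n_row_levels, n_col_levels, n_replicates): rows are
    training sets, columns classifiers, replicates the per-class metric
    values per trial.  The F statistic reported is the row (training-set)
    factor's.  Fitted via an OLS two-factor interaction model.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 3:
        raise ValueError(
            "expected a (rows, columns, replicates) array; unbalanced "
            "designs are not supported"
        )
    a, b, r = table.shape
    if a < 2 or b < 2:
        raise ValueError("each factor needs at least 2 levels")
    if r < 2:
        raise ValueError("need at least 2 replicates per cell")
    rows, cols, values = [], [], []
    for i in range(a):
        for j in range(b):
            for k in range(r):
                rows.append(i)
                cols.append(j)
                values.append(table[i, j, k])
    df = pd.DataFrame({"row": rows, "col": cols, "y": values})
    degenerate = bool(np.allclose(table.var(axis=2), 0.0))
    model = ols("y ~ C(row) * C(col)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    f_ratio = float(anova.loc["C(row)", "F"])
    p_value = float(anova.loc["C(row)", "PR(>F)"])
    df_factor = a - 1
    df_error = a * b * (r - 1)
    return AnovaResult(
        f_ratio=f_ratio,
        critical_f=critical_f(df_factor, df_error, alpha),
        p_value=p_value,
        df_factor=df_factor,
        df_error=df_error,
        degenerate=degenerate,
    )
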