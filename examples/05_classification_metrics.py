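"""Per-class classification metrics and the two-way ANOVA with
replication used to compare training sets across classifiers.
"""

import numpy as np

from respaug.classification_eval import (
    anova_two_way,
    confusion,
    critical_f,
    per_class_metrics,
)

true = ["COPD"] * 8 + ["URTI"] * 8
pred = ["COPD"] * 7 + ["URTI"] + ["URTI"] * 6 + ["COPD"] * 2
cm = confusion(true, pred, class_labels=("COPD", "URTI"))
print("confusion matrix (rows = true):")
print(cm)
m = per_class_metrics(cm, class_labels=("COPD", "URTI"))
print(m.frame().round(3))

# 4 training sets x 5 classifiers, 21 replicates per cell (7 classes x 3
# trials); a synthetic table with a real training-set effect
rng = np.random.default_rng(0)
table = rng.normal(scale=0.1, size=(4, 5, 21))
table[1:] += 0.08  # augmented sets shift the metric up
res = anova_two_way(table)
print(f"\ntwo-way ANOVA, training-set factor: F = {res.f_ratio:.2f}, "
      f"critical F(0.95; {res.df_factor}, {res.df_error}) = "
      f"{res.critical_f:.2f}, p = {res.p_value:.2e}")
print(f"critical F for the standard design: "
      f"{critical_f(3, 400):.2f} (df 3, 400)")
print("F above the critical value means the training sets differ "
      "significantly on this metric.")
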