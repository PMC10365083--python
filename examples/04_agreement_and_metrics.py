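"""Ordinal metrics and inter/intra-rater agreement coefficients.

MA-MAE weighs misgradings by how many grades off they are and averages
within each true grade before averaging across grades, so it is robust
to class imbalance.  Fleiss' kappa measures chance-corrected agreement
among multiple raters; the quadratically weighted Cohen kappa penalises
a two-grade disagreement four times as much as a one-grade one.
"""

import numpy as np

from koosgrade import (
    fleiss_kappa,
    ma_mae,
    metrics_report,
    weighted_kappa_quadratic,
)

rng = np.random.default_rng(0)
truth = rng.integers(1, 5, size=60)
# a grader that is sometimes one grade off
pred = np.clip(truth + rng.choice([0, 0, 0, 0, 1, -1], size=60), 1, 4)

report = metrics_report(truth, pred)
print(f"accuracy     : {report.accuracy:.3f}")
print(f"weighted F1  : {report.weighted_f1:.3f}")
print(f"MA-MAE       : {report.ma_mae:.3f}   (mean grades-off per class)")
print("confusion (rows = truth, cols = prediction):")
print(report.confusion.to_frame().to_string(), "\n")

# two raters with correlated but imperfect gradings
r1 = np.clip(truth + rng.choice([0, 0, 1, -1], size=60), 1, 4)
r2 = np.clip(truth + rng.choice([0, 0, 1, -1], size=60), 1, 4)
print(f"Fleiss kappa (2 raters)        : {fleiss_kappa(np.column_stack([r1, r2])):.3f}")
print(f"quadratic weighted Cohen kappa : {weighted_kappa_quadratic(r1, r2):.3f}")
print(f"exact off-by-one MA-MAE check  : {ma_mae([1,1,2], [1,2,2]):.3f} (hand value 0.25)")
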