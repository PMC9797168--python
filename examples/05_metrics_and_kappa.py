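"""Evaluation metrics: confusion matrix, precision/recall, Cohen's kappa.

Works through the chance-corrected-agreement arithmetic on a small
confusion matrix and shows the micro-averaging identity.
"""

import numpy as np

from gacnn import accuracy, kappa, precision_recall, report, sweep_report

C = np.array([[40, 10], [20, 30]])
k, p0, pe = kappa(C)
print(f"confusion {C.tolist()}: p0 = {p0:.2f}, pe = {pe:.2f}, "
      f"kappa = (p0 - pe)/(1 - pe) = {k:.2f}")

prec, rec = precision_recall(C, "micro")
print(f"micro precision {prec:.2f} = micro recall {rec:.2f} "
      f"= accuracy {accuracy(C):.2f}")
# Micro averaging pools one-vs-rest counts, which is why recall equals
# accuracy in every cell of a single-label multi-class report.

rng = np.random.default_rng(0)
truth = rng.integers(0, 5, 100)
noisy = np.where(rng.random(100) < 0.7, truth, rng.integers(0, 5, 100))
rep = report(truth, noisy, 5)
print(f"5-class example: accuracy {rep.accuracy:.2f}, kappa {rep.kappa:.2f}")

table = sweep_report({0.05: [rep.as_dict()], 1.0: [rep.as_dict()]})
print(table.to_string(index=False))
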