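"""Evaluate BMD predictions the way a bone-density reading is used
clinically: agreement statistics, T-score conversion, and WHO
reclassification (normal / osteopenia / osteoporosis).

Works on a synthetic predictions table so it runs instantly; the same code
path consumes any predictions CSV produced by the cross-validation runner.
"""

import numpy as np
import pandas as pd

from clavibmd import evaluation as ev

rng = np.random.default_rng(0)
n = 400
sex = np.where(rng.random(n) < 0.695, "female", "male")
gt = np.clip(rng.normal(0.898, 0.188, n), 0.3, 1.5)
pred = gt + rng.normal(-0.01, 0.09, n)   # small bias, realistic error

preds = pd.DataFrame({"bmd_true": gt, "bmd_pred": pred, "sex": sex})

print(f"MAE: {ev.mae(preds):.3f} g/cm²,  R: {ev.pearson_r(preds):.3f}")
ba = ev.bland_altman(preds)
print(f"Bland–Altman bias {ba.bias:+.3f}, limits of agreement "
      f"[{ba.loa_low:+.3f}, {ba.loa_high:+.3f}] g/cm²")

# diagnostic boundaries implied by the female reference values
print(f"female BMD at T = -2.5: {ev.bmd_from_tscore(-2.5, 'female'):.3f} g/cm²")
print(f"female BMD at T = -1.0: {ev.bmd_from_tscore(-1.0, 'female'):.3f} g/cm²")

gt_cls = [ev.classify_who(ev.tscore(b, s)) for b, s in zip(gt, sex)]
pr_cls = [ev.classify_who(ev.tscore(b, s)) for b, s in zip(pred, sex)]
rep = ev.classification_report(gt_cls, pr_cls)
print("confusion matrix (rows = truth, cols = predicted; "
      "osteoporosis / osteopenia / normal):")
print(rep.confusion)
for cls in ev.WHO_CLASSES:
    m = rep.per_class[cls]
    print(f"{cls:>12}: sens {m['sensitivity']:.3f}  spec {m['specificity']:.3f}  "
          f"prec {m['precision']:.3f}  F1 {m['f1']:.3f}")
print("macro:", {k: round(v, 3) for k, v in rep.macro.items()})
# The macro row is the unweighted mean of the three class rows; boundary
# cases land exactly per the WHO rules (T = -2.5 is osteoporosis,
# T = -1.0 is normal).
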