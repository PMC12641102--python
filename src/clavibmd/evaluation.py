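"""Agreement and reclassification statistics for BMD predictions.

Covers MAE, Pearson R, evaluation Dice, Bland–Altman bias / limits of
agreement, a LOWESS trend of absolute error against true BMD, T-score
conversion against sex-specific young-adult reference values, WHO
three-class reclassification (normal / osteopenia / osteoporosis) with
classwise and macro-averaged metrics, and the paired model comparison
(Shapiro–Wilk normality gate, then Wilcoxon signed-rank or paired t-test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

OSTEOPOROSIS = "osteoporosis"
OSTEOPENIA = "osteopenia"
NORMAL = "normal"
WHO_CLASSES = (OSTEOPOROSIS, OSTEOPENIA, NORMAL)


@dataclass
class ReferenceValues:
    """Sex-specific young-adult mean (YAM) and SD of lumbar BMD, g/cm²."""

    yam_male: float = 1.024
    sd_male: float = 0.131
    yam_female: float = 1.010
    sd_female: float = 0.119

    def validate(self) -> None:
        for v in (self.yam_male, self.sd_male, self.yam_female, self.sd_female):
            if not v > 0:
                raise ValueError("reference values must be positive")

    def for_sex(self, sex: str) -> tuple[float, float]:
        if sex == "male":
            return self.yam_male, self.sd_male
        if sex == "female":
            return self.yam_female, self.sd_female
        raise ValueError(f"unknown sex {sex!r}")


@dataclass
class AgreementStats:
    bias: float
    loa_low: float
    loa_high: float


@dataclass
class ClassificationReport:
    confusion: np.ndarray          # 3x3, rows = truth, cols = predicted
    classes: tuple = WHO_CLASSES
    per_class: dict = field(default_factory=dict)
    macro: dict = field(default_factory=dict)
    has_undefined: bool = False


def _pairs(records) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, pd.DataFrame):
        gt = records["bmd_true"].to_numpy(dtype=float) if "bmd_true" in records \
            else records["bmd_gt"].to_numpy(dtype=float)
        pred = records["bmd_pred"].to_numpy(dtype=float)
    else:
        gt, pred = (np.asarray(a, dtype=float) for a in records)
    if gt.size != pred.size:
        raise ValueError("prediction/ground-truth length mismatch")
    return gt, pred


def mae(records) -> float:
    """Mean absolute error (1/n) Σ |BMD_pred − BMD_gt|, g/cm²."""
    gt, pred = _pairs(records)
    if gt.size == 0:
        raise ValueError("mae needs at least one pair")
    return float(np.mean(np.abs(pred - gt)))


def pearson_r(records) -> float:
    """Product-moment correlation between predicted and true BMD."""
    gt, pred = _pairs(records)
    if gt.size < 3:
        raise ValueError("pearson_r needs at least 3 pairs")
    if np.var(gt) == 0 or np.var(pred) == 0:
        raise ValueError("pearson_r undefined for zero-variance input")
    return float(stats.pearsonr(pred, gt).statistic)


def dice_eval(s_pred: np.ndarray, s_gt: np.ndarray,
              threshold: float = 0.5) -> float:
    """Hard Dice coefficient after binarizing the soft map at ``threshold``."""
    s_pred = np.asarray(s_pred, dtype=float)
    s_gt = np.asarray(s_gt)
    if s_pred.shape != s_gt.shape:
        raise ValueError("shape mismatch")
    x = s_pred >= threshold
    y = s_gt > 0
    denom = int(x.sum()) + int(y.sum())
    if denom == 0:
        raise ValueError("Dice undefined: both masks empty")
    return 2.0 * float((x & y).sum()) / denom


def bland_altman(records) -> AgreementStats:
    """Bias and 95 % limits of agreement (bias ± 1.96·sample SD) of the
    differences BMD_pred − BMD_gt."""
    gt, pred = _pairs(records)
    if gt.size < 2:
        raise ValueError("bland_altman needs at least 2 pairs")
    d = pred - gt
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementStats(bias=bias, loa_low=bias - 1.96 * sd,
                          loa_high=bias + 1.96 * sd)


def lowess_error_trend(records, frac: float = 0.3, it: int = 3) -> np.ndarray:
    """LOWESS-smoothed |BMD_pred − BMD_gt| as a function of BMD_gt.

    Returns an (m, 2) array of (bmd_gt, smoothed absolute error) at the m
    distinct observed BMD_gt values, sorted ascending.
    """
    gt, pred = _pairs(records)
    if gt.size < 5:
        raise ValueError("lowess_error_trend needs at least 5 pairs")
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must be in (0, 1]")
    fitted = sm_lowess(np.abs(pred - gt), gt, frac=frac, it=it,
                       return_sorted=True)
    frame = pd.DataFrame(fitted, columns=["bmd_gt", "abs_err"])
    out = frame.groupby("bmd_gt", sort=True)["abs_err"].mean().reset_index()
    return out.to_numpy()


def tscore(bmd: float, sex: str, refs: ReferenceValues | None = None) -> float:
    """T-score = (BMD − YAM) / SD with sex-specific references."""
    refs = refs or ReferenceValues()
    refs.validate()
    yam, sd = refs.for_sex(sex)
    return (float(bmd) - yam) / sd


def bmd_from_tscore(t: float, sex: str,
                    refs: ReferenceValues | None = None) -> float:
    """Inverse of :func:`tscore`: BMD = YAM + t·SD."""
    refs = refs or ReferenceValues()
    refs.validate()
    yam, sd = refs.for_sex(sex)
    return yam + float(t) * sd


def classify_who(t: float) -> str:
    """WHO class from a T-score: normal (T ≥ −1.0), osteopenia
    (−2.5 < T < −1.0), osteoporosis (T ≤ −2.5)."""
    t = float(t)
    if not np.isfinite(t):
        raise ValueError("T-score must be finite")
    if t <= -2.5:
        return OSTEOPOROSIS
    if t >= -1.0:
        return NORMAL
    return OSTEOPENIA


def classification_report(gt_classes, pred_classes) -> ClassificationReport:
    """One-vs-rest sensitivity/specificity/precision/F1 per WHO class and
    their unweighted macro means.

    Cells with zero denominators are NaN, flagged, and excluded from the
    macro averages with a warning.
    """
    gt = list(gt_classes)
    pred = list(pred_classes)
    if len(gt) != len(pred):
        raise ValueError("length mismatch")
    for label in gt + pred:
        if label not in WHO_CLASSES:
            raise ValueError(f"unknown class label {label!r}")
    idx = {c: i for i, c in enumerate(WHO_CLASSES)}
    confusion = np.zeros((3, 3), dtype=int)
    for g, p in zip(gt, pred):
        confusion[idx[g], idx[p]] += 1

    report = ClassificationReport(confusion=confusion)
    n = confusion.sum()
    for i, cls in enumerate(WHO_CLASSES):
        tp = confusion[i, i]
        fn = confusion[i, :].sum() - tp
        fp = confusion[:, i].sum() - tp
        tn = n - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        prec = tp / (tp + fp) if tp + fp else np.nan
        f1 = 2 * prec * sens / (prec + sens) \
            if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0 \
            else np.nan
        report.per_class[cls] = {"sensitivity": sens, "specificity": spec,
                                 "precision": prec, "f1": f1}
    for metric in ("sensitivity", "specificity", "precision", "f1"):
        vals = np.array([report.per_class[c][metric] for c in WHO_CLASSES])
        if np.isnan(vals).any():
            report.has_undefined = True
            warnings.warn(f"undefined {metric} for an empty class; "
                          "excluded from the macro average")
        report.macro[metric] = float(np.nanmean(vals))
    return report


def macro_average(class_values) -> float:
    """Unweighted mean of classwise metric values."""
    vals = np.asarray(list(class_values), dtype=float)
    if vals.size == 0:
        raise ValueError("macro_average needs at least one value")
    return float(vals.mean())


@dataclass
class ModelComparison:
    normality_p: float
    test_name: str
    p_value: float
    significant: bool


def compare_models(abs_errors_a, abs_errors_b, alpha: float = 0.05
                   ) -> ModelComparison:
    """Paired comparison of two models' absolute errors.

    Shapiro–Wilk on the paired differences gates the test choice: if
    normality is rejected at 0.05, a two-sided Wilcoxon signed-rank test
    is used (as in the reference protocol); otherwise a paired t-test.
    """
    a = np.asarray(abs_errors_a, dtype=float).ravel()
    b = np.asarray(abs_errors_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 6:
        raise ValueError("compare_models needs at least 6 pairs")
    d = a - b
    if np.allclose(d, 0.0):
        return ModelComparison(normality_p=1.0, test_name="degenerate",
                               p_value=1.0, significant=False)
    normality_p = float(stats.shapiro(d).pvalue)
    if normality_p < 0.05:
        res = stats.wilcoxon(a, b, alternative="two-sided")
        name = "wilcoxon_signed_rank"
    else:
        res = stats.ttest_rel(a, b)
        name = "paired_t"
    p = float(res.pvalue)
    return ModelComparison(normality_p=normality_p, test_name=name,
                           p_value=p, significant=bool(p < alpha))
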