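"""ROC diagnostic-accuracy analysis: AUC, Youden cutoff, likelihood ratio.

Evaluates how well a single continuous variable separates the positive class
(high resilience) from the negative class.  The curve is built over midpoint
thresholds; the orientation (whether larger or smaller values indicate the
positive class) is selected so AUC >= 0.5 and recorded as a ">" or "<"
decision rule.  AUC uses the trapezoid rule (equal to the rank statistic
U / (n1 n2)); its CI and p-value against AUC = 0.5 use the Hanley-McNeil
standard error.  The operating point maximizes the Youden index
J = sensitivity + specificity - 1, with Wilson-score CIs on sensitivity and
specificity, and the positive likelihood ratio LR+ = sens / (1 - spec).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

_Z975 = sps.norm.ppf(0.975)


def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion k/n."""
    if n == 0:
        raise ValueError("n must be positive")
    z = sps.norm.ppf(0.5 + conf / 2)
    phat = k / n
    denom = 1 + z ** 2 / n
    centre = (phat + z ** 2 / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z ** 2 / (4 * n ** 2)) / denom
    lo = 0.0 if k == 0 else max(0.0, centre - half)
    hi = 1.0 if k == n else min(1.0, centre + half)  # exact at the boundaries
    return lo, hi


def likelihood_ratio(sens: float, spec: float) -> float:
    """Positive likelihood ratio LR+ = sensitivity / (1 - specificity).

    Perfect specificity gives an infinite ratio, returned as ``math.inf``.
    """
    if not (0 <= sens <= 1 and 0 <= spec <= 1):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    if spec == 1.0:
        return math.inf
    return sens / (1.0 - spec)


@dataclass
class RocCurve:
    """ROC points with the thresholds that generate them.

    ``orientation`` is ">" when values above a cutoff call the positive
    class, "<" when values below do.  ``fpr``/``tpr`` are sorted ascending
    and include the (0,0) and (1,1) endpoints.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray   # aligned with fpr/tpr; +/- inf at the endpoints
    orientation: str
    n_pos: int
    n_neg: int

    @property
    def auc(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


def roc_curve(scores, labels, positive="high") -> RocCurve:
    """Build the ROC curve of a score against binary class labels.

    ``labels`` may be booleans or the strings "high"/"low"; ``positive``
    names the positive class.  Thresholds are midpoints between consecutive
    distinct scores plus infinite sentinels; orientation is chosen so that
    AUC >= 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    is_pos = labels == positive if labels.dtype.kind in "UOS" else labels.astype(bool)
    n_pos = int(is_pos.sum())
    n_neg = int(is_pos.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2 if distinct.size > 1 else np.array([])

    def points(orient: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        thr = np.concatenate([[-np.inf], mids, [np.inf]])
        fpr, tpr = [], []
        for t in thr:
            called = scores > t if orient == ">" else scores < t
            tpr.append(called[is_pos].sum() / n_pos)
            fpr.append(called[~is_pos].sum() / n_neg)
        fpr, tpr, thr = np.array(fpr), np.array(tpr), np.array(thr)
        order = np.lexsort((tpr, fpr))
        return fpr[order], tpr[order], thr[order]

    fpr_g, tpr_g, thr_g = points(">")
    auc_g = float(np.trapezoid(tpr_g, fpr_g))
    if auc_g >= 0.5:
        return RocCurve(fpr_g, tpr_g, thr_g, ">", n_pos, n_neg)
    fpr_l, tpr_l, thr_l = points("<")
    return RocCurve(fpr_l, tpr_l, thr_l, "<", n_pos, n_neg)


def auc_ci(curve: RocCurve, conf: float = 0.95) -> tuple[float, tuple[float, float], float, bool]:
    """(AUC, CI, two-sided p vs 0.5, degenerate flag) by Hanley-McNeil.

    A single distinct score (curve with no interior threshold) is degenerate:
    AUC = 0.5 with a collapsed CI, flagged True.
    """
    a = curve.auc
    n1, n2 = curve.n_pos, curve.n_neg
    if curve.thresholds.size <= 2:  # only the sentinels: no usable cutoff
        return 0.5, (0.5, 0.5), 1.0, True
    q1 = a / (2 - a)
    q2 = 2 * a ** 2 / (1 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a ** 2) + (n2 - 1) * (q2 - a ** 2)) / (n1 * n2)
    se = math.sqrt(max(var, 0.0))
    z = sps.norm.ppf(0.5 + conf / 2)
    lo, hi = max(0.0, a - z * se), min(1.0, a + z * se)
    p = 1.0 if se == 0 and a == 0.5 else (0.0 if se == 0 else
                                          float(2 * sps.norm.sf(abs(a - 0.5) / se)))
    return a, (lo, hi), p, False


def youden_optimal(curve: RocCurve) -> dict:
    """Operating point maximizing J = sens + spec - 1.

    Ties are broken toward higher sensitivity, then the lower cutoff.
    Sensitivity and specificity carry Wilson-score 95% CIs.
    """
    sens = curve.tpr
    spec = 1.0 - curve.fpr
    j = sens + spec - 1.0
    best = j.max()
    tied = np.flatnonzero(j >= best - 1e-12)
    tied = tied[sens[tied] >= sens[tied].max() - 1e-12]
    finite = curve.thresholds[tied]
    i = tied[int(np.argmin(finite))]
    k_tp = int(round(sens[i] * curve.n_pos))
    k_tn = int(round(spec[i] * curve.n_neg))
    return {
        "cutoff": float(curve.thresholds[i]),
        "direction": curve.orientation,
        "sensitivity": float(sens[i]),
        "sensitivity_ci": wilson_interval(k_tp, curve.n_pos),
        "specificity": float(spec[i]),
        "specificity_ci": wilson_interval(k_tn, curve.n_neg),
        "j": float(j[i]),
    }


@dataclass
class RocResult:
    variable: str
    auc: float
    auc_ci: tuple[float, float]
    p: float
    cutoff: float
    direction: str
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    j: float
    lr_plus: float
    degenerate: bool = False
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "variable": self.variable, "auc": self.auc,
            "auc_ci": list(self.auc_ci), "p": self.p,
            "cutoff": self.cutoff, "direction": self.direction,
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci),
            "j": self.j, "degenerate": self.degenerate,
            "lr_plus": ("inf" if math.isinf(self.lr_plus) else self.lr_plus),
        }
        d.update(self.extras)
        return d


def roc_analysis(scores, labels, positive="high", variable: str = "") -> RocResult:
    """Full single-variable diagnostic evaluation (curve, AUC, Youden, LR+)."""
    curve = roc_curve(scores, labels, positive=positive)
    a, ci, p, degenerate = auc_ci(curve)
    opt = youden_optimal(curve)
    return RocResult(
        variable=variable, auc=a, auc_ci=ci, p=p,
        cutoff=opt["cutoff"], direction=opt["direction"],
        sensitivity=opt["sensitivity"], sensitivity_ci=opt["sensitivity_ci"],
        specificity=opt["specificity"], specificity_ci=opt["specificity_ci"],
        j=opt["j"], lr_plus=likelihood_ratio(opt["sensitivity"], opt["specificity"]),
        degenerate=degenerate)
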