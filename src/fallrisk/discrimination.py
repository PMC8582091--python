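"""ROC machinery for discriminating recurrent fallers.

The classification rule is "positive (recurrent) if score >= threshold".
The ROC curve sweeps every unique observed score plus sentinels; the AUC is
the trapezoid area over (1-specificity, sensitivity), which equals the
Mann-Whitney probability that a random recurrent faller scores above a
random occasional faller (ties counted half).  The optimal cutoff maximises
Youden's J = sensitivity + specificity - 1.

Confidence intervals: Hanley-McNeil for the AUC (bootstrap optional),
Wilson score intervals for sensitivity/specificity, and percentile
bootstrap over participants for the predictive values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ROCResult",
    "ConfusionSummary",
    "roc_curve",
    "auc_mann_whitney",
    "youden_cutoff",
    "auc_band",
    "auc_ci",
    "confusion_at",
]


@dataclass
class ROCResult:
    thresholds: np.ndarray      # ascending; includes -inf and +inf sentinels
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    youden_cutoff: float
    youden_index: float
    band: str

    @property
    def youden(self) -> tuple[float, float, float]:
        """(cutoff, sensitivity, specificity) at the Youden-optimal threshold."""
        i = int(np.where(self.thresholds == self.youden_cutoff)[0][0])
        return self.youden_cutoff, float(self.sensitivity[i]), float(self.specificity[i])


@dataclass
class ConfusionSummary:
    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    ppv_ci: tuple[float, float]
    npv_ci: tuple[float, float]


def _check_inputs(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be aligned")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be 0/1")
    return scores, labels


def auc_mann_whitney(scores, labels) -> float:
    """P(score_pos > score_neg) + 1/2 P(tie), via midranks (O(n log n))."""
    scores, labels = _check_inputs(scores, labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _curve(scores: np.ndarray, labels: np.ndarray):
    thresholds = np.concatenate([[-np.inf], np.unique(scores), [np.inf]])
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # rule: positive if score >= threshold
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    return thresholds, sens, spec


def roc_curve(scores, labels, ci: bool = True) -> ROCResult:
    """Full ROC analysis of a score against the recurrent-faller indicator.

    ``labels`` is the dichotomous classification (recurrent = 1,
    occasional = 0).
    """
    scores, labels = _check_inputs(scores, labels)
    thresholds, sens, spec = _curve(scores, labels)
    # trapezoid over (1 - specificity, sensitivity); sort by x then y for
    # a well-defined polyline
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))
    auc = float(np.trapezoid(sens[order], fpr[order]))

    j = sens + spec - 1.0
    best = int(np.flatnonzero(j == j.max())[0])  # ties -> lowest threshold
    cutoff = float(thresholds[best])

    low, high = auc_ci(scores, labels) if ci else (float("nan"), float("nan"))
    return ROCResult(thresholds=thresholds, sensitivity=sens,
                     specificity=spec, auc=auc, auc_ci_low=low,
                     auc_ci_high=high, youden_cutoff=cutoff,
                     youden_index=float(j[best]), band=auc_band(auc))


def youden_cutoff(roc: ROCResult) -> tuple[float, float, float]:
    """(cutoff, sensitivity, specificity) maximising J = sens + spec - 1."""
    return roc.youden


def auc_band(auc: float) -> str:
    """Interpretation band for an AUC.

    0.5 is chance (noninformative); (0.5, 0.7] less accurate; (0.7, 0.9]
    moderately accurate; (0.9, 1.0) highly accurate; 1.0 perfect.  AUCs
    below 0.5 (worse than chance) are reported as noninformative.
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"AUC must lie in [0, 1], got {auc}")
    if auc == 1.0:
        return "perfect"
    if auc > 0.9:
        return "highly_accurate"
    if auc > 0.7:
        return "moderately_accurate"
    if auc > 0.5:
        return "less_accurate"
    return "noninformative"


def auc_ci(scores, labels, level: float = 0.95, method: str = "hanley",
           n_boot: int = 2000, seed: int = 0) -> tuple[float, float]:
    """Confidence interval for the AUC.

    ``method="hanley"`` (default) uses the Hanley-McNeil standard error;
    ``method="bootstrap"`` resamples participants and takes percentile
    bounds.  Bounds are clipped to [0, 1].
    """
    scores, labels = _check_inputs(scores, labels)
    a = auc_mann_whitney(scores, labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if method == "hanley":
        q1 = a / (2 - a)
        q2 = 2 * a ** 2 / (1 + a)
        var = (a * (1 - a) + (n_pos - 1) * (q1 - a ** 2)
               + (n_neg - 1) * (q2 - a ** 2)) / (n_pos * n_neg)
        z = stats.norm.ppf(0.5 + level / 2)
        half = z * math.sqrt(max(var, 0.0))
        lo, hi = a - half, a + half
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = len(scores)
        draws = []
        while len(draws) < n_boot:
            idx = rng.integers(0, n, n)
            lab = labels[idx]
            if lab.min() == lab.max():
                continue  # resample lacking a class is redrawn
            draws.append(auc_mann_whitney(scores[idx], lab))
        alpha = (1 - level) / 2
        lo, hi = np.quantile(draws, [alpha, 1 - alpha])
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))


def confusion_at(scores, labels, cutoff: float, n_boot: int = 2000,
                 seed: int = 0, level: float = 0.95) -> ConfusionSummary:
    """Confusion counts and rate CIs at a fixed cutoff (rule: >= cutoff).

    Sensitivity and specificity get Wilson score intervals; PPV and NPV get
    percentile-bootstrap intervals from participant-level resampling at the
    fixed cutoff.  If the cutoff sends every participant to one class, the
    predictive value of the empty class is NaN (with a warning).
    """
    scores, labels = _check_inputs(scores, labels)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    pred = scores >= cutoff
    pos = labels == 1
    tp = int((pred & pos).sum())
    fp = int((pred & ~pos).sum())
    fn = int((~pred & pos).sum())
    tn = int((~pred & ~pos).sum())

    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    sens_ci = proportion_confint(tp, tp + fn, alpha=1 - level, method="wilson")
    spec_ci = proportion_confint(tn, tn + fp, alpha=1 - level, method="wilson")

    def _pv(tp_, fp_, tn_, fn_):
        ppv_ = tp_ / (tp_ + fp_) if (tp_ + fp_) else np.nan
        npv_ = tn_ / (tn_ + fn_) if (tn_ + fn_) else np.nan
        return ppv_, npv_

    ppv, npv = _pv(tp, fp, tn, fn)
    if math.isnan(ppv) or math.isnan(npv):
        warnings.warn("cutoff classifies every participant into one class; "
                      "the empty class's predictive value is undefined")

    rng = np.random.default_rng(seed)
    n = len(scores)
    boot_ppv, boot_npv = [], []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        p_, l_ = scores[idx] >= cutoff, labels[idx] == 1
        bp, bn = _pv(int((p_ & l_).sum()), int((p_ & ~l_).sum()),
                     int((~p_ & ~l_).sum()), int((~p_ & l_).sum()))
        if not math.isnan(bp):
            boot_ppv.append(bp)
        if not math.isnan(bn):
            boot_npv.append(bn)
    alpha = (1 - level) / 2

    def _pct(vals):
        if not vals:
            return (float("nan"), float("nan"))
        return tuple(float(q) for q in np.quantile(vals, [alpha, 1 - alpha]))

    return ConfusionSummary(
        cutoff=float(cutoff), tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec, ppv=float(ppv), npv=float(npv),
        sensitivity_ci=(float(sens_ci[0]), float(sens_ci[1])),
        specificity_ci=(float(spec_ci[0]), float(spec_ci[1])),
        ppv_ci=_pct(boot_ppv), npv_ci=_pct(boot_npv))
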