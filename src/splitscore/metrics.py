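"""Diagnostic evaluation: confusion metrics, ROC/AUC, reproducibility QC.

Cancer is the positive class throughout, and the ROC positivity rule is
``score >= threshold`` to match the panel's ``>= T`` decision.  AUC is the
trapezoidal area under the (FPR, TPR) sweep over all distinct score values,
which equals the Mann-Whitney statistic with ties counted 1/2.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import scipy.stats

from ._utils import CANCER, as_cancer_mask

_RATE_DEFS = {
    "sensitivity": ("tp", "fn"),
    "specificity": ("tn", "fp"),
    "ppv": ("tp", "fp"),
    "npv": ("tn", "fn"),
}


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts with derived diagnostic rates (cancer = positive).

    A rate whose denominator is zero is undefined and reported as NaN —
    never silently as 0; :meth:`is_defined` exposes the flag.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def _rate(self, num: int, den: int) -> float:
        return num / den if den else math.nan

    @property
    def sensitivity(self) -> float:
        return self._rate(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._rate(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self._rate(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._rate(self.tn, self.tn + self.fn)

    @property
    def accuracy(self) -> float:
        return self._rate(self.tp + self.tn, self.n)

    def is_defined(self, rate: str) -> bool:
        if rate == "accuracy":
            return self.n > 0
        a, b = _RATE_DEFS[rate]
        return (getattr(self, a) + getattr(self, b)) > 0

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
        }

    def as_percentages(self, ndigits: int = 1) -> dict:
        """Rates as percentages rounded to ``ndigits`` decimals (NaN kept)."""
        out = {}
        for k in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            v = getattr(self, k)
            out[k] = round(100.0 * v, ndigits) if not math.isnan(v) else math.nan
        return out

    def summary(self) -> str:
        pct = self.as_percentages()
        lines = [
            f"n={self.n}  tp={self.tp} fp={self.fp} tn={self.tn} fn={self.fn}",
            "  ".join(f"{k}={pct[k]:.1f}%" for k in pct),
        ]
        return "\n".join(lines)


def confusion(predicted, labels) -> ConfusionMetrics:
    """Confusion metrics from predicted vs true group labels."""
    pred = np.asarray(predicted)
    true = np.asarray(labels)
    if pred.shape != true.shape:
        raise ValueError(
            f"predicted ({pred.shape}) and labels ({true.shape}) differ in length"
        )
    p = pred == CANCER if pred.dtype != bool else pred
    t = true == CANCER if true.dtype != bool else true
    return ConfusionMetrics(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


@dataclass(frozen=True)
class ROCCurve:
    """Threshold sweep (positive iff score >= threshold) and its AUC.

    Points run from the all-negative operating point (threshold +inf,
    FPR=TPR=0) down to the all-positive one (threshold = min score,
    FPR=TPR=1); TPR and FPR are non-decreasing along the sweep.
    """

    thresholds: tuple[float, ...]
    tpr: tuple[float, ...]
    fpr: tuple[float, ...]
    auc: float

    @property
    def points(self) -> list[tuple[float, float, float]]:
        return list(zip(self.thresholds, self.tpr, self.fpr))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"threshold": self.thresholds, "tpr": self.tpr, "fpr": self.fpr}
        )


def roc_from_scores(scores, labels) -> ROCCurve:
    """ROC curve and AUC from per-sample scores (higher = more cancer-like).

    Ties are grouped at a single operating point; the AUC (trapezoidal rule)
    then equals P(score_cancer > score_control) + 1/2 P(tie).
    """
    s = np.asarray(scores, dtype=float)
    mask = as_cancer_mask(labels)  # raises on single-class input
    npos = int(mask.sum())
    nneg = int((~mask).sum())

    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1]))
    ge = s[None, :] >= thresholds[:, None]
    tp = (ge & mask[None, :]).sum(axis=1)
    fp = (ge & ~mask[None, :]).sum(axis=1)
    tpr = tp / npos
    fpr = fp / nneg
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(
        thresholds=tuple(float(t) for t in thresholds),
        tpr=tuple(float(t) for t in tpr),
        fpr=tuple(float(f) for f in fpr),
        auc=auc,
    )


class PearsonResult(NamedTuple):
    r: float
    p_value: float


def pearson_correlation(x, y) -> PearsonResult:
    """Product-moment correlation with a two-sided p-value (t transform).

    Used as the slide-reproducibility QC statistic (intra-/inter-slide
    concordance of normalized intensities).  Requires length >= 3 and
    non-zero variance in both vectors.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise ValueError("x and y must have the same length")
    if xv.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = scipy.stats.pearsonr(xv, yv)
    return PearsonResult(r=float(res.statistic), p_value=float(res.pvalue))
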