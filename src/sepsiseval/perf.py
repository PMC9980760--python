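"""Diagnostic-accuracy statistics.

2×2 measures with exact (Clopper-Pearson) confidence intervals, AUROC
for binary indicators and for graded scores, and DeLong's test for
paired AUROCs.  Full precision is kept internally; half-up decimal
rounding is applied only for display.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm, rankdata
from statsmodels.stats.proportion import proportion_confint


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (so 0.25 → 0.3 at 1 dp), for display."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(slots=True)
class TwoByTwo:
    """Confusion counts for a binary indicator against a binary reference."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty 2x2 table")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn


@dataclass(slots=True)
class Estimate:
    """A proportion with its 95% confidence interval."""

    point: float
    lo: float
    hi: float

    def pct(self, ndigits: int = 1) -> str:
        return (f"{round_half_up(100 * self.point, ndigits)}% "
                f"({round_half_up(100 * self.lo, ndigits)}-"
                f"{round_half_up(100 * self.hi, ndigits)})")


@dataclass(slots=True)
class DiagnosticPerformance:
    sensitivity: Optional[Estimate] = None
    specificity: Optional[Estimate] = None
    ppv: Optional[Estimate] = None
    npv: Optional[Estimate] = None
    auroc: Optional[Estimate] = None
    table: Optional[TwoByTwo] = None
    undefined: tuple = field(default_factory=tuple)


def two_by_two(predicted: Sequence, truth: Sequence) -> TwoByTwo:
    """Confusion counts from paired boolean vectors."""
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must have equal length")
    p = np.asarray(predicted, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    return TwoByTwo(tp=int(np.sum(p & t)), fp=int(np.sum(p & ~t)),
                    fn=int(np.sum(~p & t)), tn=int(np.sum(~p & ~t)))


def _proportion_ci(k: int, n: int, method: str) -> Estimate:
    sm_method = {"clopper-pearson": "beta", "wilson": "wilson"}[method]
    lo, hi = proportion_confint(k, n, alpha=0.05, method=sm_method)
    return Estimate(point=k / n, lo=float(lo), hi=float(hi))


def accuracy_stats(t: TwoByTwo,
                   ci_method: str = "clopper-pearson") -> DiagnosticPerformance:
    """Sensitivity/specificity/PPV/NPV with 95% CIs.

    A statistic whose denominator is zero is left as None and listed in
    ``undefined`` rather than silently reported as 0.
    """
    perf = DiagnosticPerformance(table=t)
    undefined = []
    pairs = {"sensitivity": (t.tp, t.tp + t.fn),
             "specificity": (t.tn, t.tn + t.fp),
             "ppv": (t.tp, t.tp + t.fp),
             "npv": (t.tn, t.tn + t.fn)}
    for name, (k, n) in pairs.items():
        if n == 0:
            undefined.append(name)
        else:
            setattr(perf, name, _proportion_ci(k, n, ci_method))
    perf.undefined = tuple(undefined)
    return perf


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------

def binary_auroc(t: TwoByTwo) -> Estimate:
    """AUROC of a yes/no indicator: (sensitivity + specificity)/2.

    Geometrically the trapezoidal area through (0,0), (1−spec, sens)
    and (1,1).  The CI uses the DeLong variance of the two-valued
    predictor (equivalently of the Mann-Whitney kernel).
    """
    if t.positives == 0 or t.negatives == 0:
        raise ValueError("binary AUROC requires both classes present")
    sens = t.tp / t.positives
    spec = t.tn / t.negatives
    auc = (sens + spec) / 2.0
    scores = np.concatenate([np.ones(t.tp), np.zeros(t.fn),
                             np.ones(t.fp), np.zeros(t.tn)])
    labels = np.concatenate([np.ones(t.tp + t.fn), np.zeros(t.fp + t.tn)])
    var = _delong_variance(scores, labels.astype(bool))
    se = math.sqrt(var)
    return Estimate(point=auc, lo=max(0.0, auc - 1.959963985 * se),
                    hi=min(1.0, auc + 1.959963985 * se))


def empirical_auroc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """AUROC across all score values: P(case > control) + ½·P(tie).

    Computed by the rank (Mann-Whitney) method; identical to trapezoidal
    integration of the empirical ROC with ties handled by mid-ranks.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("empirical AUROC requires both classes present")
    ranks = rankdata(s)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_curve(scores: Sequence[float],
              labels: Sequence[bool]) -> list[tuple[float, float, float]]:
    """Empirical ROC staircase as (FPR, TPR, threshold) triples.

    Thresholds sweep the unique score values from high to low; a point
    is the operating characteristic of the rule ``score >= threshold``.
    Starts at (0, 0, +inf) and ends at (1, 1, min score).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-s, kind="mergesort")
    s, y = s[order], y[order]
    curve = [(0.0, 0.0, math.inf)]
    tp = fp = 0
    i = 0
    while i < len(s):
        thr = s[i]
        while i < len(s) and s[i] == thr:
            tp += int(y[i])
            fp += int(not y[i])
            i += 1
        curve.append((fp / n0, tp / n1, float(thr)))
    return curve


# ---------------------------------------------------------------------------
# DeLong's test for paired AUROCs
# ---------------------------------------------------------------------------

def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Case and control placement values and the AUROC.

    The placement of a case is the fraction of controls it outranks
    (ties count half), and symmetrically for controls.
    """
    cases, controls = scores[y], scores[~y]
    n1, n0 = len(cases), len(controls)
    ranks = rankdata(np.concatenate([cases, controls]))
    case_ranks, control_ranks = ranks[:n1], ranks[n1:]
    v10 = (case_ranks - rankdata(cases)) / n0        # per-case placements
    v01 = 1.0 - (control_ranks - rankdata(controls)) / n1
    auc = float(v10.mean())
    return v10, v01, auc


def _delong_variance(scores: np.ndarray, y: np.ndarray) -> float:
    v10, v01, _ = _placements(np.asarray(scores, float), np.asarray(y, bool))
    n1, n0 = len(v10), len(v01)
    s10 = v10.var(ddof=1) if n1 > 1 else 0.0
    s01 = v01.var(ddof=1) if n0 > 1 else 0.0
    return s10 / n1 + s01 / n0


def auroc_with_ci(scores: Sequence[float], labels: Sequence[bool]) -> Estimate:
    """Empirical AUROC with the DeLong 95% confidence interval."""
    s, y = np.asarray(scores, float), np.asarray(labels, bool)
    auc = empirical_auroc(s, y)
    se = math.sqrt(_delong_variance(s, y))
    return Estimate(point=auc, lo=max(0.0, auc - 1.959963985 * se),
                    hi=min(1.0, auc + 1.959963985 * se))


@dataclass(slots=True)
class DeLongResult:
    auroc_a: Estimate
    auroc_b: Estimate
    z: float
    p_two_sided: float


def delong_test(scores_a: Sequence[float], scores_b: Sequence[float],
                labels: Sequence[bool]) -> DeLongResult:
    """DeLong's test for two correlated AUROCs measured on the same subjects.

    Uses the placement-value covariance estimator; the statistic
    z = (AUC_a − AUC_b)/SE(difference) is referred to the standard
    normal.  Identical score vectors have zero-variance difference and
    return z = 0, p = 1 with a warning.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("paired scores and labels must have equal length")
    if y.all() or not y.any():
        raise ValueError("DeLong test requires both classes present")

    v10a, v01a, auc_a = _placements(a, y)
    v10b, v01b, auc_b = _placements(b, y)
    n1, n0 = len(v10a), len(v01a)
    # covariance matrices of the paired placement vectors
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if n1 > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n0 > 1 else np.zeros((2, 2))
    cov = s10 / n1 + s01 / n0
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]

    ci_a = Estimate(auc_a, max(0.0, auc_a - 1.959963985 * math.sqrt(cov[0, 0])),
                    min(1.0, auc_a + 1.959963985 * math.sqrt(cov[0, 0])))
    ci_b = Estimate(auc_b, max(0.0, auc_b - 1.959963985 * math.sqrt(cov[1, 1])),
                    min(1.0, auc_b + 1.959963985 * math.sqrt(cov[1, 1])))
    if var_diff <= 0:
        warnings.warn("zero variance of AUROC difference; returning z=0, p=1")
        return DeLongResult(ci_a, ci_b, z=0.0, p_two_sided=1.0)
    z = (auc_a - auc_b) / math.sqrt(var_diff)
    p = 2.0 * float(norm.sf(abs(z)))
    return DeLongResult(ci_a, ci_b, z=z, p_two_sided=p)
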