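"""Diagnostic-performance reporting.

Confusion counts (cancer = positive class), the standard proportions
(sensitivity, specificity, PPV, NPV, accuracy) each with a 95%
continuity-corrected Wilson score interval (the Vassarstats convention),
the empirical ROC curve with a tie-aware Mann-Whitney AUC and a
Hanley-McNeil confidence interval, and the finite-population sample-size
formula used to plan the cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(predictions, labels) -> ConfusionTable:
    """2x2 counts from aligned boolean prediction/label vectors."""
    predictions = np.asarray(predictions, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    if predictions.shape != labels.shape:
        raise ValueError(
            f"length mismatch: {predictions.shape} predictions vs {labels.shape} labels"
        )
    return ConfusionTable(
        tp=int((predictions & labels).sum()),
        fp=int((predictions & ~labels).sum()),
        tn=int((~predictions & ~labels).sum()),
        fn=int((~predictions & labels).sum()),
    )


def wilson_cc_interval(
    successes: int, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Continuity-corrected Wilson score interval, clipped to [0, 1].

    The Newcombe (1998) form; at 0/n the lower bound is exactly 0 and at
    n/n the upper bound exactly 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError(f"successes must be in [0, {n}], got {successes}")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    p = successes / n
    denom = 2.0 * (n + z * z)
    if successes == 0:
        lower = 0.0
    else:
        lower = (2 * n * p + z * z - 1
                 - z * math.sqrt(z * z - 2 - 1 / n + 4 * p * (n * (1 - p) + 1))) / denom
    if successes == n:
        upper = 1.0
    else:
        upper = (2 * n * p + z * z + 1
                 + z * math.sqrt(z * z + 2 - 1 / n + 4 * p * (n * (1 - p) - 1))) / denom
    return max(lower, 0.0), min(upper, 1.0)


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its CI and the counts it came from."""

    proportion: float
    lower: float
    upper: float
    numerator: int
    denominator: int

    def percent(self, digits: int = 1) -> tuple[float, float, float]:
        """(estimate, lower, upper) as percentages, rounded half-up."""
        q = Decimal(10) ** -digits

        def r(x: float) -> float:
            return float(Decimal(repr(float(x) * 100)).quantize(q, rounding=ROUND_HALF_UP))

        return r(self.proportion), r(self.lower), r(self.upper)


def _estimate(num: int, den: int, confidence: float) -> MetricEstimate | None:
    if den == 0:
        return None  # undefined, never reported as 0
    lo, hi = wilson_cc_interval(num, den, confidence)
    return MetricEstimate(num / den, lo, hi, num, den)


@dataclass(frozen=True)
class DiagnosticMetrics:
    table: ConfusionTable
    sensitivity: MetricEstimate | None
    specificity: MetricEstimate | None
    ppv: MetricEstimate | None
    npv: MetricEstimate | None
    accuracy: MetricEstimate | None

    def to_dict(self) -> dict:
        out: dict = {"tp": self.table.tp, "fp": self.table.fp,
                     "tn": self.table.tn, "fn": self.table.fn}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            est = getattr(self, name)
            if est is None:
                out[name] = None
            else:
                pct, lo, hi = est.percent()
                out[name] = {"percent": pct, "ci": [lo, hi],
                             "counts": [est.numerator, est.denominator]}
        return out


def diagnostic_metrics(
    table: ConfusionTable, confidence: float = 0.95
) -> DiagnosticMetrics:
    """Point estimates + continuity-corrected Wilson CIs from a 2x2 table."""
    return DiagnosticMetrics(
        table=table,
        sensitivity=_estimate(table.tp, table.tp + table.fn, confidence),
        specificity=_estimate(table.tn, table.tn + table.fp, confidence),
        ppv=_estimate(table.tp, table.tp + table.fp, confidence),
        npv=_estimate(table.tn, table.tn + table.fn, confidence),
        accuracy=_estimate(table.tp + table.tn, table.total, confidence),
    )


@dataclass
class RocResult:
    points: pd.DataFrame      # columns fpr, tpr, threshold
    auc: float
    ci: tuple[float, float]


def roc_auc(scores, labels, confidence: float = 0.95) -> RocResult:
    """Empirical ROC curve with tie-aware Mann-Whitney AUC.

    AUC is the probability a random cancer sample outscores a random
    non-cancer sample, ties counted one half (equals the trapezoidal area
    under the empirical ROC). The CI uses the Hanley-McNeil standard error,
    clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")

    ranks = stats.rankdata(scores)
    auc = (ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    fpr, tpr, thr = roc_curve(labels.astype(int), scores)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})

    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    se = math.sqrt(
        (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2))
        / (n1 * n0)
    )
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    ci = (max(auc - z * se, 0.0), min(auc + z * se, 1.0))
    return RocResult(points=points, auc=float(auc), ci=ci)


@dataclass(frozen=True)
class SampleSizeParams:
    """Inputs of the finite-population sample-size formula."""

    population: float        # N
    mean: float              # reference mean of the planning variable
    sd: float                # its standard deviation
    t_crit: float            # critical t value
    error: float             # absolute sampling error

    def __post_init__(self):
        for name in ("population", "mean", "sd", "t_crit", "error"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.error >= self.mean:
            raise ValueError("sampling error must be below the mean")


def sample_size(params: SampleSizeParams) -> tuple[float, int]:
    """n = (N s^2 t^2) / ((N - 1) e^2 + s^2 t^2); returns (raw, ceiling)."""
    num = params.population * params.sd**2 * params.t_crit**2
    den = (params.population - 1) * params.error**2 + params.sd**2 * params.t_crit**2
    n = num / den
    return n, math.ceil(n)
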