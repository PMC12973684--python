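"""Evaluation statistics for depth-based PRDI/NRI discrimination.

Implements the full evaluation used to judge whether breath-minimum depth
separates post-regurgitation deep inhalations (PRDI) from ordinary
inhalations (NRI):

* Mann-Whitney U comparison of the two depth distributions — exact
  (permutation) p-value for small problems, tie- and continuity-corrected
  normal approximation otherwise;
* confusion counts and the threshold metrics sensitivity, specificity,
  G-mean = sqrt(sens * spec) and balanced accuracy = (sens + spec) / 2;
* the ROC curve and its AUC, which for this single-score classifier is
  identical to the tie-aware concordant-pair fraction U / (n_pos * n_neg);
* a sweep over all effective thresholds with plateau-midpoint selection of
  the operating point that maximizes G-mean and balanced accuracy
  simultaneously.

The positive class is PRDI throughout and the classification score is the
negated depth (deeper minimum => higher score).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sst

from .events import NRI, PRDI, LabeledEvent
from .io import ValidationError

__all__ = [
    "ConfusionCounts",
    "ThresholdMetrics",
    "ROCResult",
    "SweepResult",
    "mann_whitney",
    "confusion_counts",
    "threshold_metrics",
    "roc_auc",
    "sweep_and_select",
]

logger = logging.getLogger(__name__)

#: Below this product of group sizes the Mann-Whitney p-value is computed
#: exactly from the permutation distribution of U (tie-aware).
EXACT_MW_LIMIT = 400


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class ThresholdMetrics:
    threshold_z: float
    sensitivity: float
    specificity: float
    gmean: float
    balanced_accuracy: float


@dataclass
class ROCResult:
    """ROC sweep: thresholds in depth z-units, ascending; (fpr, tpr) points."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass
class SweepResult:
    metrics: list[ThresholdMetrics]
    optimal_threshold_z: float
    plateau_range: tuple[float, float]
    plateau_source: str  # "joint" or "balanced_accuracy"


def _exact_mw_p(ranks2: np.ndarray, n_a: int, u2_obs: float) -> float:
    """Two-sided exact p for U under the permutation null, with ties.

    ``ranks2`` are doubled midranks (integers even with ties).  Counts the
    size-``n_a`` subsets whose U (in doubled units) is at least as far from
    the null mean as observed, via subset-sum dynamic programming.
    """
    N = len(ranks2)
    total = int(ranks2.sum())
    # ways[k][s] = number of size-k subsets with doubled-rank sum s
    ways = np.zeros((n_a + 1, total + 1))
    ways[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        kmax = n_a - 1
        # iterate k downward so each rank is used at most once
        for k in range(kmax, -1, -1):
            row = ways[k]
            nz = np.nonzero(row)[0]
            if nz.size:
                ways[k + 1, nz + r] += row[nz]
    counts = ways[n_a]
    sums = np.arange(total + 1)
    n_b = N - n_a
    # U2 = 2*U where U = #{a<b} + 0.5*ties; S = doubled rank-sum of group a
    u2 = 2 * n_a * n_b - (sums - n_a * (n_a + 1))
    mean2 = n_a * n_b
    mask = np.abs(u2 - mean2) >= abs(u2_obs - mean2) - 1e-9
    return float(counts[mask].sum() / counts.sum())


def mann_whitney(
    depths_a: Sequence[float], depths_b: Sequence[float], alternative: str = "two_sided"
) -> tuple[float, float]:
    """Mann-Whitney U test between two depth samples.

    Returns ``(U, p)`` with the orientation U = #{(a, b): a < b} + 0.5 *
    #ties — large U means group *a* is stochastically smaller (deeper).
    The p-value is exact (permutation distribution, tie-aware) when
    ``n_a * n_b <= 400`` and a tie- and continuity-corrected normal
    approximation otherwise.  Only the two-sided alternative is offered.
    """
    if alternative != "two_sided":
        raise ValidationError("only the two-sided alternative is supported")
    a = np.asarray(depths_a, dtype=float)
    b = np.asarray(depths_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = sst.rankdata(combined)
    r_a = ranks[:n_a].sum()
    u_gt = r_a - n_a * (n_a + 1) / 2.0  # #{a>b} + 0.5*ties
    u = n_a * n_b - u_gt  # #{a<b} + 0.5*ties

    if n_a * n_b <= EXACT_MW_LIMIT:
        ranks2 = np.round(2 * ranks).astype(int)
        p = _exact_mw_p(ranks2, n_a, 2.0 * u)
    else:
        N = n_a + n_b
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (N * (N - 1))
        var = n_a * n_b / 12.0 * ((N + 1) - tie_term)
        if var == 0:
            return float(u), 1.0
        mu = n_a * n_b / 2.0
        z = (abs(u - mu) - 0.5) / math.sqrt(var)
        p = min(1.0, 2.0 * sst.norm.sf(z))
    return float(u), float(p)


def confusion_counts(events: Sequence[LabeledEvent]) -> ConfusionCounts:
    """Tally the standard confusion matrix over (label, predicted) pairs."""
    tp = fp = fn = tn = 0
    for ev in events:
        if ev.predicted is None:
            raise ValidationError("every event needs a prediction before counting")
        if ev.label == PRDI:
            if ev.predicted == PRDI:
                tp += 1
            else:
                fn += 1
        else:
            if ev.predicted == PRDI:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def threshold_metrics(counts: ConfusionCounts, threshold_z: float) -> ThresholdMetrics:
    """Sensitivity, specificity, G-mean and balanced accuracy at one threshold."""
    if counts.TP + counts.FN == 0:
        raise ValidationError("no positive (PRDI) events: sensitivity undefined")
    if counts.TN + counts.FP == 0:
        raise ValidationError("no negative (NRI) events: specificity undefined")
    sens = counts.TP / (counts.TP + counts.FN)
    spec = counts.TN / (counts.TN + counts.FP)
    return ThresholdMetrics(
        threshold_z=threshold_z,
        sensitivity=sens,
        specificity=spec,
        gmean=math.sqrt(sens * spec),
        balanced_accuracy=(sens + spec) / 2.0,
    )


def _depths_by_class(events: Sequence[LabeledEvent]) -> tuple[np.ndarray, np.ndarray]:
    pos = np.array([ev.depth_z for ev in events if ev.label == PRDI])
    neg = np.array([ev.depth_z for ev in events if ev.label == NRI])
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both classes (PRDI and NRI) must be present")
    return pos, neg


def roc_auc(events: Sequence[LabeledEvent]) -> ROCResult:
    """ROC curve and AUC for depth-thresholding, PRDI positive.

    Thresholds are the distinct observed depths in ascending order (an
    event is called positive when its depth is <= the threshold), preceded
    by one threshold below the minimum so the curve starts at (0, 0).  AUC
    is the trapezoidal area, which with this construction equals the
    tie-aware concordant-pair fraction U / (n_pos * n_neg) exactly.
    """
    pos, neg = _depths_by_class(events)
    depths = np.concatenate([pos, neg])
    uniq = np.unique(depths)
    thresholds = np.concatenate([[uniq[0] - 1.0], uniq])
    tpr = np.array([(pos <= th).mean() for th in thresholds])
    fpr = np.array([(neg <= th).mean() for th in thresholds])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def _candidate_thresholds(depths: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct depths, plus one candidate
    below the minimum and one above the maximum (unambiguous under ties)."""
    uniq = np.unique(depths)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])


def _runs(indices: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous runs (start, stop inclusive) in a sorted index array."""
    runs = []
    start = prev = int(indices[0])
    for i in indices[1:]:
        i = int(i)
        if i == prev + 1:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    return runs


def sweep_and_select(events: Sequence[LabeledEvent]) -> SweepResult:
    """Sweep all effective thresholds and select the plateau midpoint.

    The optimal operating point is the maximal contiguous run of candidate
    thresholds attaining the maximum of both G-mean and balanced accuracy;
    the reported optimal threshold is the arithmetic midpoint of that run's
    endpoints.  If no candidate maximizes both simultaneously, the balanced
    accuracy plateau is used and the fallback is logged.
    """
    pos, neg = _depths_by_class(events)
    depths = np.concatenate([pos, neg])
    cands = _candidate_thresholds(depths)
    metrics = []
    for th in cands:
        tp = int((pos <= th).sum())
        fn = pos.size - tp
        fp = int((neg <= th).sum())
        tn = neg.size - fp
        metrics.append(threshold_metrics(ConfusionCounts(tp, fp, fn, tn), float(th)))
    g = np.array([m.gmean for m in metrics])
    b = np.array([m.balanced_accuracy for m in metrics])
    tol = 1e-12
    at_g = g >= g.max() - tol
    at_b = b >= b.max() - tol
    joint = at_g & at_b
    if joint.any():
        idx = np.flatnonzero(joint)
        source = "joint"
    else:
        idx = np.flatnonzero(at_b)
        source = "balanced_accuracy"
        logger.warning(
            "G-mean and balanced-accuracy maxima do not coincide; "
            "using the balanced-accuracy plateau"
        )
    runs = _runs(idx)
    # maximal contiguous run; earliest wins ties
    start, stop = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
    lo, hi = float(cands[start]), float(cands[stop])
    return SweepResult(
        metrics=metrics,
        optimal_threshold_z=(lo + hi) / 2.0,
        plateau_range=(lo, hi),
        plateau_source=source,
    )
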