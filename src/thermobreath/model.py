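"""Threshold model for depth-based PRDI detection, statsmodels-style.

:class:`PRDIThresholdModel` is built from labeled breath events (pooled
across recordings after per-recording standardization); ``fit()`` sweeps
all effective depth thresholds and returns a :class:`PRDIThresholdResults`
carrying the selected threshold, the ROC/AUC, the Mann-Whitney comparison
of the two depth distributions, per-class summaries and a ``summary()``
table.  Prediction and plotting hang off the results object.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .events import NRI, PRDI, LabeledEvent, classify
from .io import ValidationError
from .metrics import (
    SweepResult,
    confusion_counts,
    mann_whitney,
    roc_auc,
    sweep_and_select,
    threshold_metrics,
)
from .signal import BreathEvent

__all__ = ["PRDIThresholdModel", "PRDIThresholdResults"]


class PRDIThresholdModel:
    """Single-threshold classifier of breath depth into PRDI vs NRI.

    Parameters
    ----------
    events
        Labeled breath events; both classes must be present.
    """

    def __init__(self, events: Sequence[LabeledEvent]):
        if not events:
            raise ValidationError("no events supplied")
        labels = {ev.label for ev in events}
        if not {PRDI, NRI} <= labels:
            raise ValidationError("both PRDI and NRI events are required to fit a threshold")
        self.events = list(events)

    @classmethod
    def from_dataframe(cls, df, depth_col: str = "depth_z", label_col: str = "label"):
        """Build from a DataFrame with one row per event.

        Optional columns ``event_time_s`` and ``recording_id`` are carried
        through when present.
        """
        events = []
        for i, row in enumerate(df.itertuples(index=False)):
            d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
            ev = BreathEvent(
                index=i,
                time_s=float(d.get("event_time_s", i)),
                depth_z=float(d[depth_col]),
            )
            events.append(
                LabeledEvent(
                    event=ev,
                    label=str(d[label_col]),
                    recording_id=str(d.get("recording_id", "recording")),
                )
            )
        return cls(events)

    def fit(self) -> "PRDIThresholdResults":
        """Sweep thresholds, select the plateau midpoint, assemble results."""
        sweep = sweep_and_select(self.events)
        roc = roc_auc(self.events)
        pos = np.array([ev.depth_z for ev in self.events if ev.label == PRDI])
        neg = np.array([ev.depth_z for ev in self.events if ev.label == NRI])
        u, p = mann_whitney(pos, neg)
        return PRDIThresholdResults(model=self, sweep=sweep, roc=roc, u_statistic=u, p_value=p)


class PRDIThresholdResults:
    """Fitted threshold, discrimination statistics and diagnostics."""

    def __init__(self, model: PRDIThresholdModel, sweep: SweepResult, roc, u_statistic: float, p_value: float):
        self.model = model
        self.sweep = sweep
        self.roc = roc
        self.u_statistic = u_statistic
        self.p_value = p_value
        self.optimal_threshold_z = sweep.optimal_threshold_z
        self.plateau_range = sweep.plateau_range
        self.auc = roc.auc

        self._pos = np.array([ev.depth_z for ev in model.events if ev.label == PRDI])
        self._neg = np.array([ev.depth_z for ev in model.events if ev.label == NRI])
        self.n_prdi = self._pos.size
        self.n_nri = self._neg.size
        self.median_depth_prdi = float(np.median(self._pos))
        self.median_depth_nri = float(np.median(self._neg))

        predicted = classify(model.events, self.optimal_threshold_z)
        self.confusion = confusion_counts(predicted)
        m = threshold_metrics(self.confusion, self.optimal_threshold_z)
        self.sensitivity = m.sensitivity
        self.specificity = m.specificity
        self.gmean = m.gmean
        self.balanced_accuracy = m.balanced_accuracy

    # -- prediction --------------------------------------------------------
    def predict(self, depths_z, threshold_z: float | None = None) -> np.ndarray:
        """Classify depths at the fitted (or a supplied) threshold."""
        th = self.optimal_threshold_z if threshold_z is None else threshold_z
        depths_z = np.asarray(depths_z, dtype=float)
        return np.where(depths_z <= th, PRDI, NRI)

    # -- reporting ---------------------------------------------------------
    def to_report(self) -> dict:
        """Full-precision metrics report (JSON-serializable)."""
        return {
            "n_prdi": int(self.n_prdi),
            "n_nri": int(self.n_nri),
            "u_statistic": float(self.u_statistic),
            "p_value": float(self.p_value),
            "auc": float(self.auc),
            "median_depth_prdi": self.median_depth_prdi,
            "median_depth_nri": self.median_depth_nri,
            "optimal_threshold": float(self.optimal_threshold_z),
            "plateau": [float(self.plateau_range[0]), float(self.plateau_range[1])],
            "plateau_source": self.sweep.plateau_source,
            "sensitivity": float(self.sensitivity),
            "specificity": float(self.specificity),
            "gmean": float(self.gmean),
            "balanced_accuracy": float(self.balanced_accuracy),
            "confusion": {
                "TP": self.confusion.TP,
                "FP": self.confusion.FP,
                "FN": self.confusion.FN,
                "TN": self.confusion.TN,
            },
            "sweep": [
                {
                    "threshold": m.threshold_z,
                    "sens": m.sensitivity,
                    "spec": m.specificity,
                    "gmean": m.gmean,
                    "balacc": m.balanced_accuracy,
                }
                for m in self.sweep.metrics
            ],
        }

    def summary(self) -> str:
        """Human-readable summary table (metrics rounded to 2 decimals)."""
        lines = [
            "PRDI depth-threshold model",
            "=" * 46,
            f"{'events (PRDI / NRI)':<30}{self.n_prdi} / {self.n_nri}",
            f"{'median depth PRDI (z)':<30}{self.median_depth_prdi:.2f}",
            f"{'median depth NRI (z)':<30}{self.median_depth_nri:.2f}",
            f"{'Mann-Whitney U':<30}{self.u_statistic:.1f}",
            f"{'p-value (two-sided)':<30}{self.p_value:.3g}",
            f"{'AUC':<30}{self.auc:.2f}",
            "-" * 46,
            f"{'optimal threshold (z)':<30}{self.optimal_threshold_z:.2f}",
            f"{'plateau':<30}[{self.plateau_range[0]:.2f}, {self.plateau_range[1]:.2f}]",
            f"{'sensitivity':<30}{self.sensitivity:.2f}",
            f"{'specificity':<30}{self.specificity:.2f}",
            f"{'G-mean':<30}{self.gmean:.2f}",
            f"{'balanced accuracy':<30}{self.balanced_accuracy:.2f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------
    def plot_roc(self, ax=None):
        """ROC curve with the AUC in the legend."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.roc.fpr, self.roc.tpr, label=f"AUC = {self.auc:.2f}")
        ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax

    def plot_metric_curves(self, ax=None):
        """G-mean and balanced accuracy vs threshold, optimum marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        th = [m.threshold_z for m in self.sweep.metrics]
        ax.plot(th, [m.gmean for m in self.sweep.metrics], label="G-mean")
        ax.plot(th, [m.balanced_accuracy for m in self.sweep.metrics], label="balanced accuracy")
        ax.axvline(self.optimal_threshold_z, color="k", ls=":", lw=0.8, label="optimal threshold")
        ax.set_xlabel("depth threshold (z)")
        ax.set_ylabel("metric")
        ax.legend()
        return ax
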