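"""One-class performance metrics with bootstrap confidence intervals.

All functions take anomaly scores (higher = more anomalous) and labels in
{-1 acceptable, +1 unacceptable}.  The constrained metrics are exact: every
threshold between consecutive unique scores is a candidate (plus sentinels
below the minimum and above the maximum), a plan is called anomalous when its
score exceeds the threshold, and the constrained optimum is taken over the
full sweep.

* ``Sens80`` — maximum sensitivity subject to specificity >= 0.80
* ``Spec80`` — maximum specificity subject to sensitivity >= 0.80
* ``Sens100`` / ``Spec100`` — same with the floor at 1.0
* ``AUC`` — probability a random unacceptable plan outscores a random
  acceptable one, ties counted half.

``bootstrap_metrics`` resamples the scored test set with replacement B times
(stratified within each class so both classes are present in every
replicate) and reports the mean of each metric with a 95% t-distribution
confidence half-width, ``t_{0.975, B-1} * sd / sqrt(B)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .data_model import LABEL_ACCEPTABLE, LABEL_UNACCEPTABLE

__all__ = [
    "METRIC_NAMES",
    "MetricsReport",
    "auc",
    "sens_at_spec",
    "spec_at_sens",
    "compute_metrics",
    "bootstrap_metrics",
    "roc_points",
]

METRIC_NAMES = ("Spec100", "Spec80", "Sens100", "Sens80", "AUC")


def _check(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D vectors")
    if not (
        (labels == LABEL_UNACCEPTABLE).any() and (labels == LABEL_ACCEPTABLE).any()
    ):
        raise ValueError("metrics need both classes present")
    return scores, labels


def _sweep(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sensitivity and specificity at every midpoint threshold (+- sentinels)."""
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    pos = scores[labels == LABEL_UNACCEPTABLE]
    neg = scores[labels == LABEL_ACCEPTABLE]
    # anomalous iff score > threshold
    sens = (pos[None, :] > thresholds[:, None]).mean(axis=1)
    spec = (neg[None, :] <= thresholds[:, None]).mean(axis=1)
    return sens, spec


def auc(scores, labels) -> float:
    """Area under the ROC curve; ties counted one half."""
    scores, labels = _check(scores, labels)
    return float(roc_auc_score(labels == LABEL_UNACCEPTABLE, scores))


def sens_at_spec(scores, labels, spec_floor: float) -> float:
    """Maximum sensitivity over thresholds with specificity >= ``spec_floor``."""
    scores, labels = _check(scores, labels)
    sens, spec = _sweep(scores, labels)
    feasible = spec >= spec_floor
    return float(sens[feasible].max()) if feasible.any() else 0.0


def spec_at_sens(scores, labels, sens_floor: float) -> float:
    """Maximum specificity over thresholds with sensitivity >= ``sens_floor``."""
    scores, labels = _check(scores, labels)
    sens, spec = _sweep(scores, labels)
    feasible = sens >= sens_floor
    return float(spec[feasible].max()) if feasible.any() else 0.0


def compute_metrics(scores, labels) -> dict[str, float]:
    """All five one-class metrics on a single scored test set."""
    return {
        "Spec100": spec_at_sens(scores, labels, 1.0),
        "Spec80": spec_at_sens(scores, labels, 0.8),
        "Sens100": sens_at_spec(scores, labels, 1.0),
        "Sens80": sens_at_spec(scores, labels, 0.8),
        "AUC": auc(scores, labels),
    }


@dataclass
class MetricsReport:
    """Bootstrap means and 95% t-CI half-widths of the one-class metrics."""

    estimates: dict[str, float]
    half_widths: dict[str, float]
    n_bootstrap: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": list(self.estimates),
                "estimate": [self.estimates[k] for k in self.estimates],
                "ci95_half_width": [self.half_widths[k] for k in self.estimates],
            }
        )

    def __str__(self) -> str:
        parts = [
            f"{k}: {self.estimates[k]:.2f}±{self.half_widths[k]:.2f}"
            for k in METRIC_NAMES
        ]
        return ", ".join(parts)


def bootstrap_metrics(scores, labels, n_bootstrap: int = 100, seed: int = 0) -> MetricsReport:
    """Stratified bootstrap of the five metrics with a 95% t-interval.

    Resampling is with replacement within each class, which keeps every
    replicate two-class and the metrics defined.
    """
    scores, labels = _check(scores, labels)
    rng = np.random.default_rng(seed)
    pos = scores[labels == LABEL_UNACCEPTABLE]
    neg = scores[labels == LABEL_ACCEPTABLE]
    reps = {name: np.empty(n_bootstrap) for name in METRIC_NAMES}
    for b in range(n_bootstrap):
        s = np.concatenate(
            [
                rng.choice(neg, size=neg.size, replace=True),
                rng.choice(pos, size=pos.size, replace=True),
            ]
        )
        lab = np.concatenate(
            [
                np.full(neg.size, LABEL_ACCEPTABLE),
                np.full(pos.size, LABEL_UNACCEPTABLE),
            ]
        )
        for name, value in compute_metrics(s, lab).items():
            reps[name][b] = value
    t_crit = stats.t.ppf(0.975, df=n_bootstrap - 1)
    estimates = {name: float(vals.mean()) for name, vals in reps.items()}
    half_widths = {
        name: float(t_crit * vals.std(ddof=1) / np.sqrt(n_bootstrap))
        for name, vals in reps.items()
    }
    return MetricsReport(
        estimates=estimates,
        half_widths=half_widths,
        n_bootstrap=n_bootstrap,
        seed=seed,
    )


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold) for plotting or CSV export."""
    scores, labels = _check(scores, labels)
    fpr, tpr, thr = roc_curve(labels == LABEL_UNACCEPTABLE, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
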