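"""Seeded generator of plan-like feature tables with planted structure.

The generator emulates the shape of clinical plan-QA data: few samples, many
features, heavy class imbalance, features grouped into categories (ROI /
dose / machine), a planted subset of features that is nearly constant across
acceptable plans, and anomalies that deviate on a category-specific subset of
those planted features.

Features are emitted directly on the normalized [0,1] scale (the generator
models data *after* min-max normalization): planted stable features are a
per-feature center plus uniform noise of half-range ``tau_stable``, all other
features are iid uniform on [0,1].  Anomalies first follow the acceptable
generative law, then a shift ``delta`` is added to a fraction ``rho`` of the
target category's planted features (clipped to [0, 1.5]).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import OartConfig
from .data_model import LABEL_ACCEPTABLE, LABEL_UNACCEPTABLE, FeatureTable, OneClassSplit, split_one_class
from .evaluation import auc
from .scoring import SigmaEnsemble, category_breakdown, fit_ensemble, oart_sigma_scores

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "RecoveryReport",
    "generate_dataset",
    "recovery_report",
    "run_synthetic_study",
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic plan-table generator.

    Defaults mirror the clinical setting at desk scale: 140 acceptable plans
    against 15 anomalies, 300 features split across the three clinical
    categories, 20 planted near-constant features per category with
    half-range ``tau_stable = 0.02``, and anomalies shifting half of one
    category's planted features by ``delta = 0.4``.
    """

    n_acceptable: int = 140
    n_anomalous: int = 15
    m_features: int = 300
    category_names: tuple[str, ...] = ("ROI", "dose", "machine")
    category_proportions: tuple[float, ...] = (0.5, 0.25, 0.25)
    n_planted_per_category: int = 20
    tau_stable: float = 0.02
    delta: float = 0.4
    rho: float = 0.5
    clip_range: tuple[float, float] = (0.0, 1.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_acceptable < 2 or self.n_anomalous < 0:
            raise ValueError("need >= 2 acceptable samples and >= 0 anomalies")
        if len(self.category_names) != len(self.category_proportions):
            raise ValueError("category names and proportions disagree")
        if abs(sum(self.category_proportions) - 1.0) > 1e-9:
            raise ValueError("category proportions must sum to 1")
        if self.tau_stable < 0:
            raise ValueError("tau_stable must be >= 0")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.n_anomalous > 0 and self.rho * self.n_planted_per_category < 1:
            raise ValueError(
                "rho * n_planted_per_category < 1: anomalies would perturb no feature"
            )

    def category_sizes(self) -> list[int]:
        """Feature count per category (largest-remainder rounding to sum m)."""
        raw = [p * self.m_features for p in self.category_proportions]
        sizes = [int(np.floor(r)) for r in raw]
        remainder = self.m_features - sum(sizes)
        order = np.argsort([s - r for s, r in zip(sizes, raw)])
        for k in order[:remainder]:
            sizes[k] += 1
        for name, size in zip(self.category_names, sizes):
            if size < self.n_planted_per_category:
                raise ValueError(
                    f"category {name!r} has {size} features, fewer than the "
                    f"{self.n_planted_per_category} planted ones"
                )
        return sizes


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks."""

    planted: dict[str, np.ndarray]  # category -> planted feature indices
    anomaly_targets: list[str]  # per anomaly (in anomaly row order)
    perturbed: list[np.ndarray]  # per anomaly: shifted feature indices
    anomaly_sample_ids: list[str] = field(default_factory=list)

    @property
    def all_planted(self) -> np.ndarray:
        return np.sort(np.concatenate(list(self.planted.values())))

    def to_json(self, path) -> None:
        payload = {
            "planted": {k: v.tolist() for k, v in self.planted.items()},
            "anomaly_targets": self.anomaly_targets,
            "perturbed": [p.tolist() for p in self.perturbed],
            "anomaly_sample_ids": self.anomaly_sample_ids,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            planted={k: np.asarray(v, int) for k, v in payload["planted"].items()},
            anomaly_targets=list(payload["anomaly_targets"]),
            perturbed=[np.asarray(p, int) for p in payload["perturbed"]],
            anomaly_sample_ids=list(payload.get("anomaly_sample_ids", [])),
        )


def generate_dataset(spec: SyntheticSpec) -> tuple[FeatureTable, GroundTruth]:
    """Draw a labeled feature table and its ground truth from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    sizes = spec.category_sizes()
    n = spec.n_acceptable + spec.n_anomalous
    m = spec.m_features

    categories: list[str] = []
    starts: list[int] = []
    offset = 0
    for name, size in zip(spec.category_names, sizes):
        categories.extend([name] * size)
        starts.append(offset)
        offset += size

    planted: dict[str, np.ndarray] = {}
    for name, size, start in zip(spec.category_names, sizes, starts):
        idx = rng.choice(size, size=spec.n_planted_per_category, replace=False)
        planted[name] = np.sort(idx) + start
    planted_all = np.concatenate(list(planted.values()))

    # acceptable generative law for all rows; anomalies are shifted afterwards
    values = rng.uniform(0.0, 1.0, size=(n, m))
    centers = rng.uniform(0.25, 0.75, size=planted_all.size)
    values[:, planted_all] = centers[None, :] + rng.uniform(
        -spec.tau_stable, spec.tau_stable, size=(n, planted_all.size)
    )

    anomaly_targets: list[str] = []
    perturbed: list[np.ndarray] = []
    n_shift = max(1, int(round(spec.rho * spec.n_planted_per_category)))
    for a in range(spec.n_anomalous):
        row = spec.n_acceptable + a
        target = spec.category_names[rng.integers(len(spec.category_names))]
        hit = rng.choice(planted[target], size=n_shift, replace=False)
        values[row, hit] += spec.delta
        anomaly_targets.append(target)
        perturbed.append(np.sort(hit))
    values[spec.n_acceptable :] = np.clip(values[spec.n_acceptable :], *spec.clip_range)

    labels = np.concatenate(
        [
            np.full(spec.n_acceptable, LABEL_ACCEPTABLE),
            np.full(spec.n_anomalous, LABEL_UNACCEPTABLE),
        ]
    )
    sample_ids = [f"acc_{i:03d}" for i in range(spec.n_acceptable)] + [
        f"anom_{i:03d}" for i in range(spec.n_anomalous)
    ]
    table = FeatureTable(
        values=values,
        sample_ids=sample_ids,
        feature_names=[f"{c}_{i:04d}" for i, c in enumerate(categories)],
        feature_category=categories,
        labels=labels,
    )
    truth = GroundTruth(
        planted=planted,
        anomaly_targets=anomaly_targets,
        perturbed=perturbed,
        anomaly_sample_ids=sample_ids[spec.n_acceptable :],
    )
    return table, truth


@dataclass
class RecoveryReport:
    """How well training recovered the planted structure."""

    planted_recovery: dict[float, float]  # sigma -> fraction of planted in F_sigma
    false_stable_rate_min_sigma: float
    test_auc: float
    attribution_accuracy: float  # fraction of anomalies with correct top category
    n_anomalies_scored: int


def recovery_report(
    ensemble: SigmaEnsemble, truth: GroundTruth, test: FeatureTable
) -> RecoveryReport:
    """Planted-feature recovery, false-stable rate, test AUC and attribution.

    ``test`` must contain both classes; attribution compares each anomaly's
    top category (by :func:`category_breakdown`) with its ground-truth target.
    """
    planted_all = truth.all_planted
    m = ensemble.m_features
    non_planted = np.setdiff1d(np.arange(m), planted_all)
    recovery = {}
    for sigma, mem in sorted(ensemble.memories.items()):
        in_stable = np.isin(planted_all, mem.stable_set)
        recovery[sigma] = float(in_stable.mean())
    sigma_min = min(ensemble.memories)
    false_stable = np.isin(non_planted, ensemble.memories[sigma_min].stable_set)
    scores = oart_sigma_scores(test.values, ensemble)
    test_auc = auc(scores, test.labels)

    id_to_target = dict(zip(truth.anomaly_sample_ids, truth.anomaly_targets))
    hits = 0
    total = 0
    for row, sid in enumerate(test.sample_ids):
        if sid not in id_to_target:
            continue
        breakdown = category_breakdown(test.values[row], ensemble)
        if breakdown and max(breakdown, key=breakdown.get) == id_to_target[sid]:
            hits += 1
        total += 1
    return RecoveryReport(
        planted_recovery=recovery,
        false_stable_rate_min_sigma=float(false_stable.mean()),
        test_auc=test_auc,
        attribution_accuracy=hits / total if total else float("nan"),
        n_anomalies_scored=total,
    )


def run_synthetic_study(
    spec: SyntheticSpec | None = None,
    config: OartConfig | None = None,
    train_fraction: float = 0.8,
) -> tuple[OneClassSplit, SigmaEnsemble, RecoveryReport, GroundTruth]:
    """Generate, split, train and evaluate one synthetic replicate.

    The generator emits features already on the normalized scale, so the
    ensemble is fitted with ``scale=False``; the split and training seeds are
    both derived from ``spec.seed``.
    """
    spec = spec or SyntheticSpec()
    table, truth = generate_dataset(spec)
    split = split_one_class(table, train_fraction=train_fraction, seed=spec.seed)
    config = config or OartConfig(seed=spec.seed)
    ensemble = fit_ensemble(split.train, config, scale=False)
    report = recovery_report(ensemble, truth, split.test)
    return split, ensemble, report, truth
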