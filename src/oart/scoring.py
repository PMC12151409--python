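"""Anomaly scoring on OART deviation features.

Three classifiers consume the deviation features ``Delta_sigma(x)``:

* the interpretable sigma-sum score (``OART+Sigma``): the raw sum of absolute
  deviations from stable memories, aggregated over the vigilance grid —
  higher means more anomalous, and the score decomposes exactly over features
  and feature categories;
* a one-class SVM ensemble over the (sigma, nu) grid, each member a
  Gaussian-kernel separator fitted on the training deviations — decision
  values are summed into ``S_bar``, higher meaning more acceptable;
* an optional reconstruction autoencoder whose per-plan mean squared
  reconstruction error is the anomaly score.

PCA / FastICA adapters are provided as comparator feature extractors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA, FastICA
from sklearn.neural_network import MLPRegressor
from sklearn.svm import OneClassSVM

from .core import OartConfig, OartModel, StableMemory, train_oart
from .data_model import (
    LABEL_ACCEPTABLE,
    FeatureTable,
    ScalingParams,
    minmax_apply,
    minmax_fit,
)

__all__ = [
    "DEFAULT_NU_GRID",
    "SigmaEnsemble",
    "OsvmEnsemble",
    "ReconstructionAutoencoder",
    "fit_ensemble",
    "oart_sigma_score",
    "oart_sigma_scores",
    "category_breakdown",
    "osvm_ensemble_fit",
    "osvm_ensemble_score",
    "osvm_ensemble_scores",
    "ae_reconstruction_score",
    "extract_baseline_features",
    "save_ensemble",
    "load_ensemble",
]

#: default one-class SVM complexity grid V = {0.01, 0.02, ..., 0.99}
DEFAULT_NU_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.01, 1.00, 0.01), 2))


@dataclass
class SigmaEnsemble:
    """Stable memories over a vigilance grid, with table metadata.

    ``scaling`` holds the min-max parameters fitted on the training plans
    (``None`` when the input is consumed on its native scale, e.g. synthetic
    tables that are generated already normalized).
    """

    memories: dict[float, StableMemory]
    feature_names: list[str] | None = None
    categories: list[str] | None = None
    scaling: ScalingParams | None = None
    config: OartConfig | None = None

    def __post_init__(self) -> None:
        if not self.memories:
            raise ValueError("ensemble needs at least one stable memory")
        ms = {mem.mean_memory.shape[0] for mem in self.memories.values()}
        if len(ms) != 1:
            raise ValueError("stable memories disagree on feature dimension")

    @property
    def sigmas(self) -> list[float]:
        return sorted(self.memories)

    @property
    def m_features(self) -> int:
        return next(iter(self.memories.values())).mean_memory.shape[0]

    def subset(self, sigmas) -> "SigmaEnsemble":
        """Restrict to a sub-grid (e.g. the sensitive half U~)."""
        keep = {float(s) for s in sigmas}
        missing = keep - set(self.memories)
        if missing:
            raise ValueError(f"sigmas not in ensemble: {sorted(missing)}")
        return SigmaEnsemble(
            memories={s: self.memories[s] for s in sorted(keep)},
            feature_names=self.feature_names,
            categories=self.categories,
            scaling=self.scaling,
            config=self.config,
        )


def fit_ensemble(
    table: FeatureTable, config: OartConfig | None = None, scale: bool = True
) -> SigmaEnsemble:
    """Train a sigma ensemble on the acceptable plans of ``table``.

    Rows labeled unacceptable (+1) are dropped; with ``scale`` set, min-max
    parameters are fitted on the training rows and stored in the ensemble so
    scoring applies the identical transform.
    """
    config = config or OartConfig()
    if table.labels is not None:
        keep = np.flatnonzero(table.labels == LABEL_ACCEPTABLE)
        if keep.size == 0:
            raise ValueError("no acceptable (-1) samples to train on")
        table = table.select_rows(keep)
    scaling = None
    values = table.values
    if scale:
        scaling = minmax_fit(table)
        values = minmax_apply(values, scaling)
    model: OartModel = train_oart(values, config)
    return SigmaEnsemble(
        memories=dict(model.memories),
        feature_names=list(table.feature_names),
        categories=list(table.feature_category),
        scaling=scaling,
        config=config,
    )


def _prepare(x: np.ndarray, ensemble: SigmaEnsemble, expect_2d: bool) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1 and expect_2d:
        x = x[None, :]
    if x.shape[-1] != ensemble.m_features:
        raise ValueError(
            f"plan has {x.shape[-1]} features, ensemble expects {ensemble.m_features}"
        )
    if ensemble.scaling is not None:
        x = minmax_apply(x, ensemble.scaling)
    return x


def oart_sigma_scores(X: np.ndarray, ensemble: SigmaEnsemble) -> np.ndarray:
    """OART+Sigma anomaly scores for a matrix of plans (higher = more anomalous)."""
    X = _prepare(X, ensemble, expect_2d=True)
    scores = np.zeros(X.shape[0])
    for mem in ensemble.memories.values():
        idx = mem.stable_set
        if idx.size:
            scores += np.abs(X[:, idx] - mem.mean_memory[idx]).sum(axis=1)
    return scores


def oart_sigma_score(x: np.ndarray, ensemble: SigmaEnsemble) -> float:
    """Summed absolute deviation from stable memories over the sigma grid."""
    return float(oart_sigma_scores(np.atleast_2d(x), ensemble)[0])


def category_breakdown(
    x: np.ndarray, ensemble: SigmaEnsemble, categories: list[str] | None = None
) -> dict[str, float]:
    """Average per-feature deviation by feature category.

    For each sigma, the mean deviation over that category's stable features;
    then averaged over the sigma values at which the category has at least
    one stable feature.  Categories with no stable feature at any sigma are
    absent from the result (not zero).
    """
    categories = categories if categories is not None else ensemble.categories
    if categories is None:
        raise ValueError("no feature categories available")
    if len(categories) != ensemble.m_features:
        raise ValueError("categories length does not match feature dimension")
    x = _prepare(np.asarray(x, float), ensemble, expect_2d=False)
    cats = np.asarray(categories)
    sums: dict[str, list[float]] = {}
    for mem in ensemble.memories.values():
        idx = mem.stable_set
        if idx.size == 0:
            continue
        dev = np.abs(x[idx] - mem.mean_memory[idx])
        for cat in np.unique(cats[idx]):
            sel = cats[idx] == cat
            sums.setdefault(str(cat), []).append(float(dev[sel].mean()))
    return {cat: float(np.mean(v)) for cat, v in sums.items()}


@dataclass
class OsvmEnsemble:
    """Per-(sigma, nu) Gaussian-kernel one-class separators on deviation space."""

    models: dict[tuple[float, float], OneClassSVM]
    nu_grid: tuple[float, ...]
    skipped_sigmas: list[float] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.models)


def osvm_ensemble_fit(
    train: np.ndarray,
    ensemble: SigmaEnsemble,
    nu_grid=None,
    kernel_gamma="scale",
) -> OsvmEnsemble:
    """Fit one separator per usable (sigma, nu) cell on training deviations.

    Sigma values with an empty stable set are skipped (and recorded).  The
    default kernel width policy is sklearn's ``"scale"``,
    ``1 / (|F_sigma| * var(Delta))``.
    """
    nu_grid = tuple(float(v) for v in (nu_grid if nu_grid is not None else DEFAULT_NU_GRID))
    if any(not 0.0 < v <= 1.0 for v in nu_grid):
        raise ValueError("nu values must lie in (0, 1]")
    X = _prepare(np.asarray(train, float), ensemble, expect_2d=True)
    models: dict[tuple[float, float], OneClassSVM] = {}
    skipped: list[float] = []
    for sigma, mem in sorted(ensemble.memories.items()):
        idx = mem.stable_set
        if idx.size == 0:
            skipped.append(sigma)
            continue
        delta = np.abs(X[:, idx] - mem.mean_memory[idx])
        for nu in nu_grid:
            svm = OneClassSVM(kernel="rbf", nu=nu, gamma=kernel_gamma)
            svm.fit(delta)
            models[(sigma, nu)] = svm
    if not models:
        raise ValueError("every sigma has an empty stable set; nothing to fit")
    return OsvmEnsemble(models=models, nu_grid=nu_grid, skipped_sigmas=skipped)


def osvm_ensemble_scores(
    X: np.ndarray, model: OsvmEnsemble, ensemble: SigmaEnsemble
) -> np.ndarray:
    """Summed decision values S_bar over all (sigma, nu) members.

    Positive means inside the acceptable region: higher = more acceptable.
    Negate for the shared "higher = more anomalous" metric orientation.
    """
    X = _prepare(np.asarray(X, float), ensemble, expect_2d=True)
    scores = np.zeros(X.shape[0])
    deltas: dict[float, np.ndarray] = {}
    for (sigma, _nu), svm in model.models.items():
        if sigma not in deltas:
            mem = ensemble.memories[sigma]
            idx = mem.stable_set
            deltas[sigma] = np.abs(X[:, idx] - mem.mean_memory[idx])
        scores += svm.decision_function(deltas[sigma])
    return scores


def osvm_ensemble_score(
    x: np.ndarray, model: OsvmEnsemble, ensemble: SigmaEnsemble
) -> float:
    return float(osvm_ensemble_scores(np.atleast_2d(x), model, ensemble)[0])


class ReconstructionAutoencoder:
    """Single-bottleneck reconstruction network for one-class scoring.

    A one-hidden-layer network with tanh activation and L2 weight decay,
    trained to reproduce its input on acceptable plans only; the per-plan
    mean squared reconstruction error is the anomaly score (higher = more
    anomalous).  Input can be the scaled feature vector or a concatenation of
    deviation features — whatever matrix is passed to :meth:`fit`.
    """

    def __init__(
        self,
        width: int = 32,
        l2: float = 1e-3,
        max_iter: int = 600,
        seed: int = 0,
    ):
        self.width = int(width)
        self.net = MLPRegressor(
            hidden_layer_sizes=(self.width,),
            activation="tanh",
            alpha=l2,
            max_iter=max_iter,
            random_state=seed,
        )
        self._fitted = False

    def fit(self, X: np.ndarray) -> "ReconstructionAutoencoder":
        X = np.asarray(X, dtype=float)
        self.net.fit(X, X)
        self._fitted = True
        return self

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("autoencoder has not been fitted")
        out = self.net.predict(np.atleast_2d(np.asarray(X, float)))
        return np.atleast_2d(out)

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return ((X - self.reconstruct(X)) ** 2).mean(axis=1)

    def training_mse(self, X: np.ndarray) -> float:
        return float(self.scores(X).mean())


def ae_reconstruction_score(x: np.ndarray, model: ReconstructionAutoencoder) -> float:
    """Mean squared reconstruction error of one plan (higher = more anomalous)."""
    return float(model.scores(np.atleast_2d(x))[0])


def select_autoencoder(
    train: np.ndarray, widths=(16, 32, 64), seed: int = 0, **kwargs
) -> ReconstructionAutoencoder:
    """Fit candidates of several widths; keep the lowest training MSE."""
    best = None
    best_mse = np.inf
    for w in widths:
        ae = ReconstructionAutoencoder(width=w, seed=seed, **kwargs).fit(train)
        mse = ae.training_mse(train)
        if mse < best_mse:
            best, best_mse = ae, mse
    return best


def extract_baseline_features(
    train: np.ndarray,
    test: np.ndarray,
    method: str = "pca",
    n_components: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """PCA / FastICA component scores fitted on train, applied to test.

    With fewer samples than features the number of components is capped at
    ``n_train`` (the decomposition cannot provide more).
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    n_train = train.shape[0]
    cap = min(n_train, train.shape[1])
    if n_components is None:
        n_components = cap
    if n_components > n_train:
        raise ValueError(
            f"n_components={n_components} exceeds the {n_train} training samples"
        )
    if method == "pca":
        dec = PCA(n_components=n_components, random_state=seed)
    elif method == "ica":
        dec = FastICA(n_components=n_components, random_state=seed, max_iter=1000)
    else:
        raise ValueError(f"unknown method {method!r}; use 'pca' or 'ica'")
    return dec.fit_transform(train), dec.transform(test)


# ---------------------------------------------------------------------------
# serialization: one JSON archive per trained ensemble

def save_ensemble(ensemble: SigmaEnsemble, path) -> None:
    payload = {
        "m_features": ensemble.m_features,
        "feature_names": ensemble.feature_names,
        "categories": ensemble.categories,
        "scaling": None
        if ensemble.scaling is None
        else {
            "minimum": ensemble.scaling.minimum.tolist(),
            "maximum": ensemble.scaling.maximum.tolist(),
        },
        "config": None
        if ensemble.config is None
        else {
            "alpha": ensemble.config.alpha,
            "gamma": ensemble.config.gamma,
            "n_rounds": ensemble.config.n_rounds,
            "epochs_per_round": ensemble.config.epochs_per_round,
            "sigma_grid": list(ensemble.config.sigma_grid),
            "seed": ensemble.config.seed,
        },
        "memories": [
            {
                "sigma": sigma,
                "stable_set": mem.stable_set.tolist(),
                "mean_memory": mem.mean_memory.tolist(),
                "survival_counts": mem.survival_counts.tolist(),
            }
            for sigma, mem in sorted(ensemble.memories.items())
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_ensemble(path) -> SigmaEnsemble:
    with open(path) as fh:
        payload = json.load(fh)
    memories = {
        float(m["sigma"]): StableMemory(
            sigma=float(m["sigma"]),
            stable_set=np.asarray(m["stable_set"], dtype=int),
            mean_memory=np.asarray(m["mean_memory"], dtype=float),
            survival_counts=np.asarray(m["survival_counts"], dtype=int),
        )
        for m in payload["memories"]
    }
    scaling = None
    if payload.get("scaling") is not None:
        scaling = ScalingParams(
            minimum=np.asarray(payload["scaling"]["minimum"], float),
            maximum=np.asarray(payload["scaling"]["maximum"], float),
        )
    config = None
    if payload.get("config") is not None:
        config = OartConfig(**{**payload["config"], "sigma_grid": tuple(payload["config"]["sigma_grid"])})
    return SigmaEnsemble(
        memories=memories,
        feature_names=payload.get("feature_names"),
        categories=payload.get("categories"),
        scaling=scaling,
        config=config,
    )
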