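"""One-class adaptive-resonance training (OART).

The learner keeps two weight vectors over the ``m`` input features: a boolean
switch ``f`` (is the feature still part of the memory?) and a real-valued
long-term memory ``z``.  A training round presents a shuffled sequence of
acceptable plans; a feature *resonates* with a plan when its value lies within
a distance ``sigma`` of the memory, in which case the memory is nudged toward
the plan,

    z_new = (1 - alpha) * z_old + alpha * x        (resonant features only)

while a non-resonant feature is switched off for the remainder of the round
(its memory frozen at the last resonant value).  Features that survive at
least a proportion ``gamma`` of ``E`` independently shuffled rounds are
*stable*; their memory is the average of the terminal values over all rounds.
Deviations ``|x - z_bar|`` on the stable set are the extracted features of a
new plan.

Per-feature updates are independent, which gives an exact scalar oracle for
the vectorized implementation and makes the stable sets nest across ``sigma``
when the per-round shuffles are shared (both properties are exercised by the
test suite).
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "U_GRID",
    "U_TILDE_GRID",
    "OartConfig",
    "MemoryState",
    "RoundResult",
    "StableMemory",
    "DeviationFeatures",
    "OartModel",
    "build_round_sequence",
    "init_memory",
    "resonance_step",
    "run_training_round",
    "extract_stable_memory",
    "train_oart",
    "compute_deviations",
]

#: full vigilance grid U = {0.01, 0.03, ..., 0.99}
U_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.01, 1.00, 0.02), 2))
#: sensitive half-grid U~ = {0.01, 0.03, ..., 0.49}
U_TILDE_GRID: tuple[float, ...] = tuple(s for s in U_GRID if s <= 0.49)

# slack for the gamma*E survival threshold: 0.9*20 evaluates to
# 18.000000000000004 in binary floating point and would otherwise exclude a
# feature surviving exactly 18 of 20 rounds
_THRESHOLD_SLACK = 1e-9


@dataclass
class OartConfig:
    """Training hyper-parameters.

    alpha
        Learning rate of the memory update, small so memories shift only
        slightly toward each resonant plan (default 0.1).  ``alpha = 0`` is
        permitted as the frozen-memory limit.
    gamma
        Survival stability proportion: a feature is stable when it survives
        at least ``gamma * n_rounds`` rounds (default 0.9).
    n_rounds
        Number of independently shuffled training rounds E (default 20).
    epochs_per_round
        Shuffled passes over the training set per round (default 2; the
        survivor count plateaus during the second pass).
    sigma_grid
        Ordered vigilance values; defaults to the full grid ``U_GRID``.
    adaptive_epochs
        If True, keep appending shuffled epochs to a round until the survivor
        count changes by less than ``plateau_tol`` (relative), up to
        ``max_epochs``.
    """

    alpha: float = 0.1
    gamma: float = 0.9
    n_rounds: int = 20
    epochs_per_round: int = 2
    sigma_grid: tuple[float, ...] = field(default_factory=lambda: U_GRID)
    seed: int = 0
    adaptive_epochs: bool = False
    plateau_tol: float = 1e-3
    max_epochs: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must lie in [0, 1)")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must lie in (0, 1]")
        if self.n_rounds < 1 or self.epochs_per_round < 1:
            raise ValueError("n_rounds and epochs_per_round must be >= 1")
        grid = tuple(float(s) for s in self.sigma_grid)
        if not grid:
            raise ValueError("sigma_grid must be non-empty")
        if any(not 0.0 < s <= 1.0 for s in grid):
            raise ValueError("sigma values must lie in (0, 1]")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("sigma_grid must be strictly increasing")
        self.sigma_grid = grid
        if self.max_epochs < self.epochs_per_round:
            raise ValueError("max_epochs must be >= epochs_per_round")


@dataclass
class MemoryState:
    """Long-term memory ``z`` and feature switches ``f``."""

    z: np.ndarray
    f: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.f = np.asarray(self.f, dtype=bool)
        if self.z.shape != self.f.shape or self.z.ndim != 1:
            raise ValueError("z and f must be matching 1-D vectors")

    def copy(self) -> "MemoryState":
        return MemoryState(self.z.copy(), self.f.copy())


@dataclass
class RoundResult:
    """Terminal weights and survivor trace of one training round."""

    terminal_f: np.ndarray
    terminal_z: np.ndarray
    survivor_count_trace: np.ndarray
    round_index: int = 0
    epoch_length: int = 0  # steps per epoch = n_train presentations


@dataclass
class StableMemory:
    """Stable feature set and averaged memory at one vigilance value."""

    sigma: float
    stable_set: np.ndarray  # sorted feature indices
    mean_memory: np.ndarray  # length m; meaningful on stable_set
    survival_counts: np.ndarray  # length m, in [0, E]

    @property
    def n_stable(self) -> int:
        return int(self.stable_set.size)


@dataclass
class DeviationFeatures:
    """|x − z̄σ| restricted to the stable set Fσ."""

    sigma: float
    values: np.ndarray  # length |Fσ|, all >= 0


def build_round_sequence(
    n_train: int, epochs_per_round: int, rng: np.random.Generator
) -> np.ndarray:
    """Concatenate ``epochs_per_round`` independently shuffled epochs.

    Every training index appears exactly once in each epoch block.
    """
    if n_train < 1:
        raise ValueError("n_train must be >= 1")
    return np.concatenate(
        [rng.permutation(n_train) for _ in range(epochs_per_round)]
    )


def init_memory(first_plan: np.ndarray) -> MemoryState:
    """Memory set to the first plan of the round, all switches active."""
    first_plan = np.asarray(first_plan, dtype=float)
    if not np.isfinite(first_plan).all():
        raise ValueError("initial plan contains non-finite values")
    return MemoryState(z=first_plan.copy(), f=np.ones(first_plan.shape[0], bool))


def resonance_step(
    state: MemoryState, x: np.ndarray, sigma: float, alpha: float
) -> MemoryState:
    """One resonance check + adaptive update against plan ``x``.

    Active features within ``sigma`` of the memory (inclusive boundary) are
    updated toward ``x``; active features beyond ``sigma`` are switched off
    with their memory frozen.  Inactive features are untouched.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != state.z.shape:
        raise ValueError("plan dimension does not match memory dimension")
    resonant = state.f & (np.abs(x - state.z) <= sigma)
    z = np.where(resonant, (1.0 - alpha) * state.z + alpha * x, state.z)
    return MemoryState(z=z, f=resonant)


def _run_round_multi(
    train: np.ndarray,
    epoch_seqs: list[np.ndarray],
    sigmas: np.ndarray,
    alpha: float,
    adaptive: bool = False,
    min_epochs: int = 2,
    plateau_tol: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run one round for all vigilance values at once over shared shuffles.

    Returns terminal ``f`` (S, m), terminal ``z`` (S, m) and the survivor
    trace (S, total_steps) where ``total_steps = len(sequence) - 1`` (the
    first element of the sequence initializes the memory and is not
    re-presented within its epoch).  With ``adaptive`` set, a vigilance value
    stops consuming epochs once its survivor count changes by less than
    ``plateau_tol`` (relative) over an epoch; its trace is padded with the
    terminal count.
    """
    sigmas = np.asarray(sigmas, dtype=float)
    n_sigma = sigmas.shape[0]
    sequence = np.concatenate(epoch_seqs)
    n_steps = sequence.size - 1
    z = np.tile(train[sequence[0]], (n_sigma, 1))
    f = np.ones(z.shape, dtype=bool)
    trace = np.zeros((n_sigma, n_steps), dtype=int)
    running = np.ones(n_sigma, dtype=bool)  # rows still consuming epochs
    prev_counts = np.full(n_sigma, z.shape[1], dtype=float)
    step = 0
    for epoch_idx, seq in enumerate(epoch_seqs):
        presented = seq[1:] if epoch_idx == 0 else seq
        for idx in presented:
            x = train[idx]
            resonant = f & (np.abs(x[None, :] - z) <= sigmas[:, None])
            if running.all():
                z = np.where(resonant, (1.0 - alpha) * z + alpha * x[None, :], z)
                f = resonant
            else:
                upd = running[:, None] & resonant
                z = np.where(upd, (1.0 - alpha) * z + alpha * x[None, :], z)
                f = np.where(running[:, None], resonant, f)
            trace[:, step] = f.sum(axis=1)
            step += 1
            if not f.any():
                # all features dead at every sigma: remaining steps are no-ops
                return f, z, trace
        if adaptive and epoch_idx + 1 >= min_epochs:
            counts = f.sum(axis=1).astype(float)
            rel = np.abs(prev_counts - counts) / np.maximum(prev_counts, 1.0)
            running = running & ~(rel < plateau_tol)
            prev_counts = counts
            if not running.any():
                break
        elif adaptive:
            prev_counts = f.sum(axis=1).astype(float)
    if step < n_steps:
        # rounds that stopped early: pad the trace with the terminal counts
        trace[:, step:] = f.sum(axis=1)[:, None]
    return f, z, trace


def run_training_round(
    train: np.ndarray,
    sigma: float,
    config: OartConfig,
    rng: np.random.Generator,
    round_index: int = 0,
) -> RoundResult:
    """One shuffled training round at a single vigilance value."""
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise ValueError("training matrix is empty")
    n = train.shape[0]
    epochs = _draw_epochs(n, config, rng)
    f, z, trace = _run_round_multi(
        train,
        epochs,
        np.asarray([sigma]),
        config.alpha,
        adaptive=config.adaptive_epochs,
        min_epochs=config.epochs_per_round,
        plateau_tol=config.plateau_tol,
    )
    return RoundResult(
        terminal_f=f[0],
        terminal_z=z[0],
        survivor_count_trace=trace[0],
        round_index=round_index,
        epoch_length=n,
    )


def _draw_epochs(
    n: int, config: OartConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    n_epochs = config.max_epochs if config.adaptive_epochs else config.epochs_per_round
    return [rng.permutation(n) for _ in range(n_epochs)]


def extract_stable_memory(
    rounds: list[RoundResult], gamma: float, sigma: float
) -> StableMemory:
    """Stable set ``{i : sum_e f_e[i] >= gamma * E}`` and round-averaged memory.

    The average runs over *all* rounds, using the frozen terminal value for
    rounds in which the feature deactivated.
    """
    if not rounds:
        raise ValueError("need at least one round result")
    m = rounds[0].terminal_f.shape[0]
    if any(r.terminal_f.shape[0] != m for r in rounds):
        raise ValueError("round results have inconsistent dimensions")
    n_rounds = len(rounds)
    counts = np.sum([r.terminal_f for r in rounds], axis=0).astype(int)
    stable = np.flatnonzero(counts >= gamma * n_rounds - _THRESHOLD_SLACK)
    mean_memory = np.mean([r.terminal_z for r in rounds], axis=0)
    return StableMemory(
        sigma=float(sigma),
        stable_set=stable,
        mean_memory=mean_memory,
        survival_counts=counts,
    )


class OartModel(Mapping):
    """Mapping ``sigma -> StableMemory`` plus per-round survivor traces."""

    def __init__(
        self,
        memories: dict[float, StableMemory],
        config: OartConfig,
        traces: dict[float, list[RoundResult]] | None = None,
        n_train: int = 0,
    ):
        self.memories = memories
        self.config = config
        self.rounds = traces or {}
        self.n_train = n_train

    def __getitem__(self, sigma: float) -> StableMemory:
        return self.memories[float(sigma)]

    def __iter__(self):
        return iter(self.memories)

    def __len__(self) -> int:
        return len(self.memories)


def train_oart(train: np.ndarray, config: OartConfig) -> OartModel:
    """Train stable memories at every vigilance value of the grid.

    All randomness flows from ``config.seed``.  The same E round shuffles are
    reused across the whole sigma grid, so the stable sets nest exactly:
    ``sigma1 <= sigma2  =>  F_sigma1 ⊆ F_sigma2``.
    """
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.size == 0:
        raise ValueError("training matrix must be a non-empty 2-D array")
    rng = np.random.default_rng(config.seed)
    sigmas = np.asarray(config.sigma_grid, dtype=float)
    n = train.shape[0]
    per_sigma_rounds: dict[float, list[RoundResult]] = {float(s): [] for s in sigmas}
    for e in range(config.n_rounds):
        epochs = _draw_epochs(n, config, rng)
        f, z, trace = _run_round_multi(
            train,
            epochs,
            sigmas,
            config.alpha,
            adaptive=config.adaptive_epochs,
            min_epochs=config.epochs_per_round,
            plateau_tol=config.plateau_tol,
        )
        for k, s in enumerate(sigmas):
            per_sigma_rounds[float(s)].append(
                RoundResult(
                    terminal_f=f[k],
                    terminal_z=z[k],
                    survivor_count_trace=trace[k],
                    round_index=e,
                    epoch_length=n,
                )
            )
    memories = {
        s: extract_stable_memory(rounds, config.gamma, s)
        for s, rounds in per_sigma_rounds.items()
    }
    return OartModel(memories, config, per_sigma_rounds, n_train=n)


def compute_deviations(x: np.ndarray, memory: StableMemory) -> DeviationFeatures:
    """Per-plan deviation |x[i] − z̄σ[i]| over the stable set Fσ."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] != memory.mean_memory.shape[0]:
        raise ValueError("plan dimension does not match memory dimension")
    idx = memory.stable_set
    return DeviationFeatures(
        sigma=memory.sigma, values=np.abs(x[idx] - memory.mean_memory[idx])
    )
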