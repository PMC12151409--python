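import numpy as np
import pytest

from oart import (
    MemoryState,
    OartConfig,
    build_round_sequence,
    compute_deviations,
    extract_stable_memory,
    init_memory,
    resonance_step,
    run_training_round,
    train_oart,
)
from oart.core import RoundResult, StableMemory, U_GRID, U_TILDE_GRID

from conftest import scalar_round_oracle


class TestRoundSequence:
    def test_each_epoch_is_a_permutation(self, rng):
        seq = build_round_sequence(3, 2, rng)
        assert len(seq) == 6
        assert sorted(seq[:3]) == [0, 1, 2]
        assert sorted(seq[3:]) == [0, 1, 2]

    def test_single_sample(self, rng):
        assert list(build_round_sequence(1, 2, rng)) == [0, 0]

    def test_same_rng_state_identical(self):
        a = build_round_sequence(10, 2, np.random.default_rng(5))
        b = build_round_sequence(10, 2, np.random.default_rng(5))
        assert (a == b).all()


class TestResonance:
    def test_init_memory(self):
        s = init_memory(np.array([0.2, 0.7]))
        assert (s.z == [0.2, 0.7]).all() and s.f.all()
        with pytest.raises(ValueError, match="finite"):
            init_memory(np.array([0.1, np.nan]))

    def test_fixed_point(self):
        s = MemoryState(z=np.array([0.3, 0.6]), f=np.array([True, True]))
        out = resonance_step(s, np.array([0.3, 0.6]), sigma=0.1, alpha=0.1)
        # alpha-convex identity: (1-a)z + az == z up to rounding
        np.testing.assert_allclose(out.z, s.z, rtol=1e-15)
        assert out.f.all()

    def test_hand_evaluated_update_and_deactivation(self):
        # feature 0 resonates: z <- 0.9*0.5 + 0.1*0.6 = 0.51
        # feature 1 deviates 0.7 > sigma=0.2: switch off, memory frozen
        s = MemoryState(z=np.array([0.5, 0.2]), f=np.array([True, True]))
        out = resonance_step(s, np.array([0.6, 0.9]), sigma=0.2, alpha=0.1)
        assert list(out.f) == [True, False]
        np.testing.assert_allclose(out.z, [0.51, 0.2], rtol=1e-15)

    def test_boundary_is_inclusive(self):
        s = MemoryState(z=np.array([0.5]), f=np.array([True]))
        out = resonance_step(s, np.array([0.7]), sigma=0.2, alpha=0.1)
        assert out.f[0]
        np.testing.assert_allclose(out.z, [0.52], rtol=1e-15)

    def test_dead_features_are_frozen(self):
        s = MemoryState(z=np.array([0.5]), f=np.array([False]))
        out = resonance_step(s, np.array([0.51]), sigma=0.5, alpha=0.1)
        assert not out.f[0] and out.z[0] == 0.5

    def test_dimension_mismatch(self):
        s = MemoryState(z=np.array([0.5]), f=np.array([True]))
        with pytest.raises(ValueError, match="dimension"):
            resonance_step(s, np.array([0.1, 0.2]), 0.1, 0.1)


class TestTrainingRound:
    def test_identical_plans_all_survive(self, rng):
        plan = rng.uniform(size=8)
        train = np.tile(plan, (10, 1))
        cfg = OartConfig(sigma_grid=(0.05,), seed=0)
        res = run_training_round(train, 0.05, cfg, np.random.default_rng(0))
        assert res.terminal_f.all()
        np.testing.assert_allclose(res.terminal_z, plan, rtol=1e-12)

    def test_alternating_feature_dies_at_first_mismatch(self):
        train = np.array([[0.0], [1.0], [0.0], [1.0]])
        cfg = OartConfig(sigma_grid=(0.2,), seed=0)
        res = run_training_round(train, 0.2, cfg, np.random.default_rng(0))
        assert not res.terminal_f.any()
        # dies at the first presented plan whose value differs from the
        # initializing plan's (deviation 1 > 0.2), and stays dead
        seq = build_round_sequence(4, 2, np.random.default_rng(0))
        first_mismatch = next(
            k for k, idx in enumerate(seq[1:]) if train[idx, 0] != train[seq[0], 0]
        )
        trace = np.asarray(res.survivor_count_trace)
        assert (trace[:first_mismatch] == 1).all()
        assert (trace[first_mismatch:] == 0).all()

    def test_sigma_one_keeps_everything(self, rng):
        train = rng.uniform(size=(15, 6))
        cfg = OartConfig(sigma_grid=(1.0,), seed=0)
        res = run_training_round(train, 1.0, cfg, np.random.default_rng(3))
        assert res.terminal_f.all()

    def test_empty_train_errors(self):
        cfg = OartConfig()
        with pytest.raises(ValueError, match="empty"):
            run_training_round(np.empty((0, 3)), 0.1, cfg, np.random.default_rng(0))

    def test_trace_non_increasing(self, rng):
        train = rng.uniform(size=(20, 10))
        cfg = OartConfig(sigma_grid=(0.3,), seed=0)
        res = run_training_round(train, 0.3, cfg, np.random.default_rng(1))
        assert (np.diff(res.survivor_count_trace) <= 0).all()

    def test_matches_scalar_oracle(self, rng):
        """Vectorized round == independent per-feature scalar simulation."""
        n, m = 12, 5
        train = rng.uniform(size=(n, m))
        sigma, alpha = 0.25, 0.1
        cfg = OartConfig(alpha=alpha, sigma_grid=(sigma,), seed=0)
        res = run_training_round(train, sigma, cfg, np.random.default_rng(9))
        seq = build_round_sequence(n, 2, np.random.default_rng(9))
        for i in range(m):
            f, z = scalar_round_oracle(train[:, i], seq, sigma, alpha)
            assert f == res.terminal_f[i]
            assert z == res.terminal_z[i]  # bitwise


class TestStableMemory:
    def _rounds(self, f_rows, z_rows):
        return [
            RoundResult(terminal_f=np.asarray(f, bool), terminal_z=np.asarray(z, float),
                        survivor_count_trace=np.asarray([int(np.sum(f))]))
            for f, z in zip(f_rows, z_rows)
        ]

    def test_gamma_threshold_with_default_parameters(self):
        # gamma=0.9, E=20: surviving 18 rounds is stable, 17 is not
        f = [[1, 1]] * 17 + [[1, 0]] * 3
        rounds = self._rounds(f, [[0.5, 0.5]] * 20)
        mem = extract_stable_memory(rounds, gamma=0.9, sigma=0.1)
        assert 0 in mem.stable_set  # 20 survivals
        assert 1 not in mem.stable_set  # 17 survivals < 18
        f18 = [[1]] * 18 + [[0]] * 2
        mem18 = extract_stable_memory(self._rounds(f18, [[0.5]] * 20), 0.9, 0.1)
        assert 0 in mem18.stable_set  # exactly 18 >= 0.9*20

    def test_single_round_degenerate(self):
        rounds = self._rounds([[1, 0]], [[0.4, 0.9]])
        mem = extract_stable_memory(rounds, gamma=0.9, sigma=0.2)
        assert list(mem.stable_set) == [0]
        np.testing.assert_allclose(mem.mean_memory, [0.4, 0.9])

    def test_memory_averages_all_rounds(self):
        rounds = self._rounds([[1], [1]], [[0.2], [0.4]])
        mem = extract_stable_memory(rounds, gamma=0.5, sigma=0.2)
        assert mem.mean_memory[0] == pytest.approx(0.3)

    def test_deviations(self):
        mem = StableMemory(
            sigma=0.1,
            stable_set=np.array([0]),
            mean_memory=np.array([0.3, 0.9]),
            survival_counts=np.array([5, 1]),
        )
        dev = compute_deviations(np.array([0.8, 0.1]), mem)
        np.testing.assert_allclose(dev.values, [0.5])
        empty = StableMemory(0.1, np.array([], int), np.array([0.3]), np.array([0]))
        assert compute_deviations(np.array([0.7]), empty).values.size == 0


class TestTrainOart:
    def test_determinism(self, rng, small_config):
        train = rng.uniform(size=(25, 12))
        a = train_oart(train, small_config)
        b = train_oart(train, small_config)
        for s in small_config.sigma_grid:
            assert (a[s].stable_set == b[s].stable_set).all()
            np.testing.assert_array_equal(a[s].mean_memory, b[s].mean_memory)

    def test_identical_plans_stable_everywhere(self, small_config):
        train = np.tile(np.linspace(0, 1, 7), (9, 1))
        model = train_oart(train, small_config)
        for s in small_config.sigma_grid:
            assert model[s].n_stable == 7

    def test_tight_features_stable_at_every_sigma(self, rng, small_config):
        # planted features with total spread below the smallest grid sigma
        train = rng.uniform(size=(20, 6))
        train[:, :3] = 0.5 + rng.uniform(-0.002, 0.002, size=(20, 3))
        model = train_oart(train, small_config)
        for s in small_config.sigma_grid:
            assert {0, 1, 2} <= set(model[s].stable_set)

    def test_sigma_nesting_with_shared_shuffles(self, rng):
        train = rng.uniform(size=(18, 15))
        cfg = OartConfig(n_rounds=5, sigma_grid=(0.1, 0.2, 0.4, 0.8), seed=2)
        model = train_oart(train, cfg)
        grids = cfg.sigma_grid
        for a, b in zip(grids, grids[1:]):
            assert set(model[a].stable_set) <= set(model[b].stable_set)
            assert (model[a].survival_counts <= model[b].survival_counts).all()

    def test_bounded_memories_and_deviations(self, rng, small_config):
        train = rng.uniform(size=(15, 8))
        model = train_oart(train, small_config)
        for s in small_config.sigma_grid:
            z = model[s].mean_memory
            assert ((z >= 0) & (z <= 1)).all()
            x = rng.uniform(-0.5, 1.5, size=8)
            dev = compute_deviations(x, model[s])
            assert (dev.values >= 0).all() and (dev.values <= 1.5).all()

    def test_zero_learning_rate_closed_form(self, rng):
        """alpha=0: feature survives iff every presented value is within
        sigma of the round's first plan."""
        n, m, sigma = 10, 6, 0.3
        train = rng.uniform(size=(n, m))
        cfg = OartConfig(alpha=0.0, sigma_grid=(sigma,), seed=0)
        res = run_training_round(train, sigma, cfg, np.random.default_rng(4))
        seq = build_round_sequence(n, 2, np.random.default_rng(4))
        first = train[seq[0]]
        expected = (np.abs(train[seq[1:]] - first) <= sigma).all(axis=0)
        assert (res.terminal_f == expected).all()
        np.testing.assert_array_equal(res.terminal_z, first)

    def test_default_grids(self):
        assert len(U_GRID) == 50 and U_GRID[0] == 0.01 and U_GRID[-1] == 0.99
        assert len(U_TILDE_GRID) == 25 and U_TILDE_GRID[-1] == 0.49

    def test_config_validation(self):
        with pytest.raises(ValueError):
            OartConfig(alpha=1.0)
        with pytest.raises(ValueError):
            OartConfig(sigma_grid=(0.3, 0.2))
        with pytest.raises(ValueError):
            OartConfig(gamma=0.0)
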