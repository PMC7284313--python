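"""Tests for the single-level ensemble simulation."""

import numpy as np
import pytest

from blanketsim.ensemble_sim import (
    SimConfig,
    differentiation_state,
    init_ensemble,
    run,
    step,
)
from blanketsim.errors import InvalidInputError
from blanketsim.model_core import (
    N_TYPES,
    Precisions,
    PriorMatrices,
    TypeIndex,
    predict,
    softmax,
)

# small, fast configuration for unit-level dynamics tests
FAST = dict(n_steps=32, snapshot_stride=8)


def states_equal(a, b) -> bool:
    return (
        np.array_equal(a.pos, b.pos)
        and np.array_equal(a.a_y, b.a_y)
        and np.array_equal(a.mu, b.mu)
    )


class TestSimConfig:
    def test_defaults_valid(self):
        SimConfig()

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_cells=0),
            dict(dt=0.0),
            dict(snapshot_stride=0),
            dict(motility_gain=-1.0),
            dict(generalized_order=3),
            dict(commit_threshold=0.2),
            dict(commit_threshold=1.0),
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(InvalidInputError):
            SimConfig(**kwargs)


class TestInitEnsemble:
    def test_deterministic(self):
        cfg = SimConfig(seed=7)
        assert states_equal(init_ensemble(cfg), init_ensemble(cfg))

    def test_pluripotency_limit(self):
        cfg = SimConfig(seed=0, init_mu_sd=0.0)
        state = init_ensemble(cfg)
        np.testing.assert_allclose(softmax(state.mu), np.full((16, 3), 1 / 3))

    def test_secretion_matches_prediction(self):
        cfg = SimConfig(seed=1)
        state = init_ensemble(cfg)
        np.testing.assert_allclose(state.a_y, predict(state.mu, cfg.priors).s_y)

    def test_position_spread_monte_carlo(self):
        # aggregated over many ensembles, the per-coordinate sd matches
        # init_pos_sd (the per-ensemble normalisation fixes the rms radius,
        # which preserves the expected spread)
        sd = 1.2
        draws = np.concatenate(
            [init_ensemble(SimConfig(seed=s, init_pos_sd=sd)).pos.ravel() for s in range(400)]
        )
        assert draws.std() == pytest.approx(sd, rel=0.05)

    def test_rms_radius_fixed_across_seeds(self):
        cfg = SimConfig()
        rms = [
            np.sqrt(np.mean(np.sum(init_ensemble(SimConfig(seed=s)).pos ** 2, axis=1)))
            for s in range(5)
        ]
        np.testing.assert_allclose(rms, cfg.init_pos_sd * np.sqrt(2.0), rtol=1e-12)

    def test_free_energy_recomputable(self):
        cfg = SimConfig(seed=2)
        state = init_ensemble(cfg)
        assert state.total_f == pytest.approx(
            float(np.sum(state.per_cell_free_energy(cfg.precisions))), abs=1e-9
        )


class TestStep:
    def test_zero_gains_leave_state_unchanged(self):
        cfg = SimConfig(
            seed=3, motility_gain=0.0, secretion_gain=0.0, belief_gain=0.0, **FAST
        )
        rng = np.random.default_rng(0)
        s0 = init_ensemble(cfg, np.random.default_rng(cfg.seed))
        s1 = step(s0, cfg, rng)
        assert states_equal(s0, s1)

    def test_fixed_point_zero_errors_zero_prior(self):
        # one isolated, noiseless, fully committed cell whose secretion
        # matches its prediction: nothing moves
        priors = PriorMatrices()
        cfg = SimConfig(
            n_cells=1,
            seed=0,
            noise_log_precision=np.inf,
            precisions=Precisions(pi_prior=0.0),
            priors=priors,
            **FAST,
        )
        mu = np.array([[30.0, 0.0, 0.0]])
        pred = predict(mu, priors)
        from blanketsim.ensemble_sim import _bookkeep

        state = _bookkeep(
            np.zeros((1, 2)), pred.s_y.copy(), mu, pred.s_y.copy(), np.zeros((1, 3)), cfg, t=0.0
        )
        out = step(state, cfg, np.random.default_rng(0))
        np.testing.assert_allclose(out.pos, state.pos, atol=1e-12)
        np.testing.assert_allclose(out.a_y, state.a_y, atol=1e-9)
        np.testing.assert_allclose(out.mu, state.mu, atol=1e-9)

    def test_secretion_converges_to_prediction(self):
        # single free cell with a pinned one-hot belief: a_y relaxes to the
        # p_y column (scalar linear ODE with rate pi_y)
        priors = PriorMatrices()
        cfg = SimConfig(
            n_cells=1,
            seed=0,
            noise_log_precision=np.inf,
            belief_gain=0.0,
            motility_gain=0.0,
            n_steps=4096,
            snapshot_stride=4096,
        )
        mu = np.array([[30.0, 0.0, 0.0]])
        from blanketsim.ensemble_sim import _bookkeep

        state = _bookkeep(
            np.zeros((1, 2)), np.zeros((1, 3)), mu, np.zeros((1, 3)), np.zeros((1, 3)), cfg, t=0.0
        )
        rng = np.random.default_rng(0)
        for _ in range(cfg.n_steps):
            state = step(state, cfg, rng)
        np.testing.assert_allclose(state.a_y, predict(mu, cfg.priors).s_y, atol=1e-6)

    def test_belief_descent_monotone_with_frozen_actions(self):
        # frozen positions/secretions, no noise: repeated belief steps
        # monotonically decrease each cell's free energy
        cfg = SimConfig(
            seed=4,
            noise_log_precision=np.inf,
            motility_gain=0.0,
            secretion_gain=0.0,
            **FAST,
        )
        state = init_ensemble(cfg, np.random.default_rng(cfg.seed))
        rng = np.random.default_rng(0)
        f_prev = state.per_cell_free_energy(cfg.precisions)
        for _ in range(20):
            state = step(state, cfg, rng)
            f = state.per_cell_free_energy(cfg.precisions)
            assert np.all(f <= f_prev + 1e-10)
            f_prev = f

    def test_blowup_reported_with_cell_index(self):
        from blanketsim.errors import NumericalBlowupError

        cfg = SimConfig(seed=0, dt=1e6, **FAST)  # absurd step size
        state = init_ensemble(cfg, np.random.default_rng(cfg.seed))
        rng = np.random.default_rng(0)
        with pytest.raises(NumericalBlowupError, match="cell"), np.errstate(all="ignore"):
            for _ in range(512):  # divergence needs ~50 steps to overflow
                state = step(state, cfg, rng)


class TestRun:
    def test_zero_steps_single_snapshot(self):
        traj = run(SimConfig(seed=0, n_steps=0))
        assert len(traj.snapshots) == 1

    def test_determinism(self):
        cfg = SimConfig(seed=9, **FAST)
        t1, t2 = run(cfg), run(cfg)
        assert all(states_equal(a, b) for a, b in zip(t1.snapshots, t2.snapshots))

    def test_times_strictly_increasing(self):
        traj = run(SimConfig(seed=0, **FAST))
        assert np.all(np.diff(traj.times) > 0)

    def test_snapshot_count(self):
        traj = run(SimConfig(seed=0, n_steps=64, snapshot_stride=16))
        assert len(traj.snapshots) == 1 + 64 // 16

    def test_order2_runs_and_tracks_mu_prime(self):
        cfg = SimConfig(seed=0, generalized_order=2, **FAST)
        traj = run(cfg)
        assert traj.snapshots[-1].mu_prime is not None


class TestTimestepStability:
    @pytest.mark.xfail(
        reason=(
            "final type assignments are not invariant to doubling dt: the"
            " sensory-noise ratchet that drives commitment makes the"
            " trajectory a function of the realised noise path, which dt"
            " changes entirely (and the per-step measurement noise doubles"
            " the effective diffusion when dt doubles); see docs/methods.md"
        ),
        strict=False,
    )
    def test_doubling_dt_preserves_final_types(self):
        from dataclasses import replace

        from blanketsim.ensemble_sim import differentiation_state

        base = SimConfig(seed=0)
        halved = replace(
            base,
            dt=base.dt * 2,
            n_steps=base.n_steps // 2,
            snapshot_stride=base.snapshot_stride // 2,
        )
        _, types_a = differentiation_state(run(base).snapshots[-1], 0.9)
        _, types_b = differentiation_state(run(halved).snapshots[-1], 0.9)
        assert types_a == types_b


class TestDifferentiationState:
    def test_uncommitted_uniform(self):
        from blanketsim.ensemble_sim import _bookkeep

        cfg = SimConfig(n_cells=1)
        state = _bookkeep(
            np.zeros((1, 2)), np.zeros((1, 3)), np.zeros((1, 3)),
            np.zeros((1, 3)), np.zeros((1, 3)), cfg, t=0.0,
        )
        committed, types = differentiation_state(state, 0.9)
        assert not committed[0] and types[0] is None

    def test_committed_sensory(self):
        from blanketsim.ensemble_sim import _bookkeep

        cfg = SimConfig(n_cells=1)
        state = _bookkeep(
            np.zeros((1, 2)), np.zeros((1, 3)), np.array([[20.0, 0.0, 0.0]]),
            np.zeros((1, 3)), np.zeros((1, 3)), cfg, t=0.0,
        )
        committed, types = differentiation_state(state, 0.9)
        assert committed[0] and types[0] is TypeIndex.SENSORY

    def test_tie_break_lowest_index(self):
        from blanketsim.ensemble_sim import _bookkeep

        cfg = SimConfig(n_cells=1)
        # exact two-way tie between active and internal, above threshold
        state = _bookkeep(
            np.zeros((1, 2)), np.zeros((1, 3)), np.array([[-40.0, 20.0, 20.0]]),
            np.zeros((1, 3)), np.zeros((1, 3)), cfg, t=0.0,
        )
        committed, types = differentiation_state(state, 0.4)
        assert committed[0] and types[0] is TypeIndex.ACTIVE

    def test_threshold_validated(self):
        state = init_ensemble(SimConfig(seed=0))
        with pytest.raises(InvalidInputError):
            differentiation_state(state, 0.3)
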