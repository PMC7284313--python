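"""Tests for the blanket diagnostics."""

import numpy as np
import pytest

from blanketsim.blanket_metrics import (
    NOT_CONVERGED,
    commit_times,
    free_energy_descent,
    independence_ratio,
    radial_ordering,
    report,
)
from blanketsim.config_io import make_fixture
from blanketsim.ensemble_sim import SimConfig, Trajectory, _bookkeep
from blanketsim.errors import InvalidInputError, MetricUndefinedError
from blanketsim.model_core import TypeIndex
from blanketsim.signal_field import DecayKernel

S, A, I = TypeIndex.SENSORY, TypeIndex.ACTIVE, TypeIndex.INTERNAL
KERNEL = DecayKernel(form="exponential", length_scale=1.0)


def ring_fixture():
    """1 internal at origin, 5 active at r=1, 10 sensory at r=2."""
    state = make_fixture("converged_level1")
    labels = [I] * 1 + [A] * 5 + [S] * 10
    return state.pos, labels


class TestRadialOrdering:
    def test_ring_fixture_ordered(self):
        pos, labels = ring_fixture()
        means, ordered = radial_ordering(pos, labels)
        assert ordered
        np.testing.assert_allclose(
            means, [2.0, 1.0, 0.0], atol=1e-12
        )  # (sensory, active, internal)

    def test_swapped_rings_not_ordered(self):
        pos, labels = ring_fixture()
        swapped = [{A: S, S: A}.get(lab, lab) for lab in labels]
        _, ordered = radial_ordering(pos, swapped)
        assert not ordered

    def test_translation_invariance(self):
        pos, labels = ring_fixture()
        means, ordered = radial_ordering(pos + np.array([10.0, -3.0]), labels)
        np.testing.assert_allclose(means, [2.0, 1.0, 0.0], atol=1e-12)
        assert ordered

    def test_missing_type_undefined(self):
        pos, labels = ring_fixture()
        no_internal = [A if lab is I else lab for lab in labels]
        with pytest.raises(MetricUndefinedError, match="INTERNAL"):
            radial_ordering(pos, no_internal)

    def test_uncommitted_cells_ignored_in_centroid(self):
        pos, labels = ring_fixture()
        pos2 = np.vstack([pos, [[50.0, 0.0]]])
        labels2 = list(labels) + [None]
        means, ordered = radial_ordering(pos2, labels2)
        np.testing.assert_allclose(means[:3], [2.0, 1.0, 0.0], atol=1e-12)
        assert ordered


class TestIndependenceRatio:
    def test_ring_fixture_closed_form(self):
        pos, labels = ring_fixture()
        # internal at the centre: distance 2 to every sensory, 1 to every active
        assert independence_ratio(pos, labels, KERNEL) == pytest.approx(
            np.exp(-2.0) / np.exp(-1.0)
        )

    def test_internal_on_sensory_ring_fails(self):
        pos, labels = ring_fixture()
        pos2 = pos.copy()
        pos2[0] = [2.0, 0.0]  # internal cell moved onto the sensory ring
        ratio = independence_ratio(pos2, labels, KERNEL)
        assert ratio >= 1.0

    def test_rigid_motion_invariance(self):
        pos, labels = ring_fixture()
        base = independence_ratio(pos, labels, KERNEL)
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = pos @ R.T + np.array([-4.0, 7.0])
        assert independence_ratio(moved, labels, KERNEL) == pytest.approx(base)

    def test_missing_type_undefined(self):
        pos, labels = ring_fixture()
        with pytest.raises(MetricUndefinedError):
            independence_ratio(pos, [A] * len(labels), KERNEL)


def synthetic_trajectory(f_values):
    cfg = SimConfig(n_cells=1, n_steps=0)
    snaps = []
    for k, f in enumerate(f_values):
        mu = np.array([[np.log(max(f, 1e-12)), 0.0, 0.0]])
        s = _bookkeep(
            np.zeros((1, 2)), np.zeros((1, 3)), np.zeros((1, 3)),
            np.zeros((1, 3)), np.zeros((1, 3)), cfg, t=float(k),
        )
        object.__setattr__(s, "total_f", float(f))
        snaps.append(s)
    return Trajectory(snapshots=snaps, config=cfg)


class TestFreeEnergyDescent:
    def test_strictly_decreasing(self):
        traj = synthetic_trajectory(np.linspace(100, 10, 50))
        ini, fin, ok = free_energy_descent(traj, window=5)
        assert ok and fin < ini

    def test_constant_series_no_descent(self):
        traj = synthetic_trajectory(np.full(50, 42.0))
        _, _, ok = free_energy_descent(traj, window=5)
        assert not ok

    def test_small_noise_tolerated(self):
        rng = np.random.default_rng(0)
        base = np.linspace(100, 10, 400)
        noisy = base + rng.normal(0, 0.02, size=base.size)  # amplitude << 1% of range
        _, _, ok = free_energy_descent(synthetic_trajectory(noisy), window=10)
        assert ok

    def test_large_rise_rejected(self):
        f = np.concatenate([np.linspace(100, 50, 20), np.linspace(90, 40, 20)])
        _, _, ok = free_energy_descent(synthetic_trajectory(f), window=1)
        assert not ok

    def test_needs_two_snapshots(self):
        with pytest.raises(InvalidInputError):
            free_energy_descent(synthetic_trajectory([1.0]), window=5)


def belief_trajectory(mu_series):
    """Trajectory of a single cell whose belief follows the given series."""
    cfg = SimConfig(n_cells=1, n_steps=0)
    snaps = [
        _bookkeep(
            np.zeros((1, 2)), np.zeros((1, 3)), np.array([mu]),
            np.zeros((1, 3)), np.zeros((1, 3)), cfg, t=float(k),
        )
        for k, mu in enumerate(mu_series)
    ]
    return Trajectory(snapshots=snaps, config=cfg)


HOT = [20.0, 0.0, 0.0]
COLD = [0.0, 0.0, 0.0]


class TestCommitTimes:
    def test_committed_from_start(self):
        traj = belief_trajectory([HOT] * 5)
        assert commit_times(traj)[0] == 0.0

    def test_crossing_and_staying(self):
        traj = belief_trajectory([COLD] * 5 + [HOT] * 5)
        assert commit_times(traj)[0] == 5.0

    def test_oscillation_reports_last_crossing(self):
        traj = belief_trajectory([COLD, HOT, COLD, HOT, HOT, HOT])
        assert commit_times(traj)[0] == 3.0

    def test_type_switch_breaks_commitment(self):
        other = [0.0, 20.0, 0.0]
        traj = belief_trajectory([HOT, HOT, other, other])
        assert commit_times(traj)[0] == 2.0

    def test_never_committed(self):
        traj = belief_trajectory([COLD] * 4)
        assert commit_times(traj)[0] == NOT_CONVERGED

    def test_truncation_monotonicity(self):
        series = [COLD] * 5 + [HOT] * 5
        full = belief_trajectory(series)
        truncated = belief_trajectory(series[:4])
        assert commit_times(full)[0] == 5.0
        assert commit_times(truncated)[0] == NOT_CONVERGED


class TestReport:
    def test_fixture_passes(self):
        cfg = SimConfig()
        rep = report(make_fixture("converged_level1"), cfg)
        assert rep.passes
        assert rep.type_counts == (10, 5, 1)
        assert rep.committed_count == 16

    def test_shuffled_fails_over_100_shuffles(self):
        cfg = SimConfig()
        fails = sum(
            not report(make_fixture("shuffled", seed=s), cfg).passes for s in range(100)
        )
        assert fails == 100

    def test_random_labels_fail_overwhelmingly(self):
        cfg = SimConfig()
        rng = np.random.default_rng(0)
        n_pass = 0
        for _ in range(100):
            pos = rng.normal(size=(16, 2))
            mu = 20.0 * np.eye(3)[rng.integers(0, 3, size=16)]
            state = _bookkeep(
                pos, np.zeros((16, 3)), mu, np.zeros((16, 3)), np.zeros((16, 3)), cfg, t=0.0
            )
            n_pass += report(state, cfg).passes
        assert n_pass == 0

    def test_deterministic(self):
        cfg = SimConfig()
        state = make_fixture("converged_level1")
        assert report(state, cfg) == report(state, cfg)

    def test_missing_type_reported_not_fatal(self):
        cfg = SimConfig()
        mu = 20.0 * np.eye(3)[[0] * 16]  # all sensory
        state = _bookkeep(
            np.zeros((16, 2)), np.zeros((16, 3)), mu,
            np.zeros((16, 3)), np.zeros((16, 3)), cfg, t=0.0,
        )
        rep = report(state, cfg)
        assert not rep.passes and np.isnan(rep.independence_ratio)
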