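"""Two-level (blanket-of-blankets) simulation via a mean-field coupling.

Sixteen ensembles self-organise at a global scale exactly as sixteen cells
do at the local scale.  Only one ensemble is simulated explicitly, cell by
cell; the other fifteen are macro-agents that run plain level-1 dynamics at
the global spatial scale.  Every cell of the explicit ensemble carries a
*second* belief — about its ensemble's global type — and a second secretion
action; the ensemble's global secretion is the average of its cells' global
actions, and every cell receives an identical copy of the ensemble's global
sensation.  Both levels share one set of prior matrices.

Randomness is split into two independent streams, one per level, so that
switching the global gains to zero reproduces the single-level simulation
bit for bit (the decoupling limit).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numpy.typing import NDArray

from . import ensemble_sim, model_core, signal_field
from .ensemble_sim import EnsembleState, SimConfig, Trajectory, _bookkeep
from .errors import InvalidInputError
from .model_core import (
    N_TYPES,
    PredictionError,
    PriorMatrices,
    SensoryState,
    belief_flow,
    free_energy,
    prediction_errors,
)

__all__ = [
    "HierarchyConfig",
    "MacroAgent",
    "HierarchyState",
    "HierarchyTrajectory",
    "shared_priors",
    "aggregate_up",
    "broadcast_down",
    "init_hierarchy",
    "step_hierarchy",
    "run_hierarchy",
]

EXPLICIT = 0  # index of the explicitly simulated ensemble among the macros

# The global gains are a quarter of the local ones, so global drift is 4x
# slower -- but the noise-driven re-sorting of an initial mis-commitment is
# diffusive and scales with the square of the step size, i.e. 16x slower.
# The default hierarchical run is therefore 16x the level-1 default length;
# see docs/methods.md ("Hierarchy").
DEFAULT_STEPS_FACTOR = 16


def _default_hier_local() -> SimConfig:
    base = SimConfig()
    return replace(
        base,
        n_steps=base.n_steps * DEFAULT_STEPS_FACTOR,
        snapshot_stride=base.snapshot_stride * DEFAULT_STEPS_FACTOR,
    )


@dataclass(frozen=True)
class HierarchyConfig:
    """Two-level configuration: a local :class:`SimConfig` plus global scales.

    The global level reuses every local parameter except that spatial scales
    (initial position spread and kernel length scale) are multiplied by
    ``global_scale`` — so ensembles are distinguishable objects — and all
    three gains are multiplied by ``global_gain`` — encoding the slower
    macroscopic timescale.  Both multipliers are configurable.  The default
    ``local`` config runs ``DEFAULT_STEPS_FACTOR`` times longer than the
    single-level default, matching the slower global convergence.
    """

    local: SimConfig = field(default_factory=_default_hier_local)
    n_ensembles: int = 16
    global_scale: float = 4.0
    global_gain: float = 0.25

    def __post_init__(self) -> None:
        if self.n_ensembles <= 0:
            raise InvalidInputError("n_ensembles must be positive")
        if self.global_scale <= 0:
            raise InvalidInputError("global_scale must be positive")
        if self.global_gain < 0:
            raise InvalidInputError("global_gain must be non-negative")

    @property
    def global_config(self) -> SimConfig:
        """The level-1 configuration the macro ensemble runs under."""
        k = self.local.kernel
        return replace(
            self.local,
            n_cells=self.n_ensembles,
            kernel=type(k)(form=k.form, length_scale=k.length_scale * self.global_scale),
            init_pos_sd=self.local.init_pos_sd * self.global_scale,
            motility_gain=self.local.motility_gain * self.global_gain,
            secretion_gain=self.local.secretion_gain * self.global_gain,
            belief_gain=self.local.belief_gain * self.global_gain,
        )


def shared_priors(cfg: HierarchyConfig) -> tuple[PriorMatrices, PriorMatrices]:
    """The identical prior matrices used at both levels (one object, twice)."""
    return cfg.local.priors, cfg.local.priors


def aggregate_up(a_y_g_cells: NDArray[np.float64]) -> NDArray[np.float64]:
    """Macro secretion: the arithmetic mean of the cells' global secretion actions."""
    a = np.asarray(a_y_g_cells, dtype=float)
    if a.ndim != 2 or a.shape[0] < 1 or a.shape[1] != N_TYPES:
        raise InvalidInputError("need an (n, 3) array with at least one cell")
    return a.mean(axis=0)


def broadcast_down(
    k: int,
    macro_pos: NDArray[np.float64],
    macro_a_y: NDArray[np.float64],
    kernel_g: signal_field.DecayKernel,
) -> NDArray[np.float64]:
    """Global extracellular sensation of macro ``k``.

    This single 3-vector is what every cell of an explicit ensemble receives
    as its global sensory input (the ensemble senses the global field once,
    as one agent).
    """
    return signal_field.extracellular_sensation(k, macro_pos, macro_a_y, kernel_g)


@dataclass(frozen=True)
class MacroAgent:
    """One ensemble as seen at the global scale (a convenience projection)."""

    id: int
    pos_g: NDArray[np.float64]
    a_y_g: NDArray[np.float64]
    mu_g: NDArray[np.float64]
    explicit: bool


@dataclass(frozen=True)
class HierarchyState:
    """Both levels at one instant.

    ``local`` is the explicit ensemble with per-cell global beliefs and
    secretion actions attached (``mu_g``, ``a_y_g``).  ``macro`` is the
    global ensemble stored as a level-1 :class:`EnsembleState`; row
    ``EXPLICIT`` is the explicit ensemble's macro-view, whose belief and
    secretion are the means over its cells (the mean-field contract).
    ``total_f`` sums the local free energy, the cells' global free energies,
    and the non-explicit macros' free energies.
    """

    local: EnsembleState
    macro: EnsembleState
    t: float
    total_f: float

    @property
    def macros(self) -> list[MacroAgent]:
        return [
            MacroAgent(
                id=k,
                pos_g=self.macro.pos[k],
                a_y_g=self.macro.a_y[k],
                mu_g=self.macro.mu[k],
                explicit=(k == EXPLICIT),
            )
            for k in range(self.macro.n_cells)
        ]


@dataclass(frozen=True)
class HierarchyTrajectory:
    """Twin trajectories (local and global) plus the hierarchy config."""

    local: Trajectory
    macro: Trajectory
    config: HierarchyConfig

    @property
    def times(self) -> NDArray[np.float64]:
        return self.local.times

    @property
    def free_energies(self) -> NDArray[np.float64]:
        """Total (local + global) free energy per snapshot."""
        return self.local.free_energies + self.macro.free_energies


def _global_rng(cfg: HierarchyConfig) -> np.random.Generator:
    # independent of the local stream default_rng(seed)
    return np.random.default_rng(np.random.SeedSequence(entropy=cfg.local.seed, spawn_key=(1,)))


def _assemble(
    local: EnsembleState,
    macro_pos: NDArray,
    macro_a_y: NDArray,
    macro_mu: NDArray,
    macro_s_y: NDArray,
    macro_s_alpha: NDArray,
    cfg: HierarchyConfig,
    t: float,
    cell_fe_g: float,
) -> HierarchyState:
    gcfg = cfg.global_config
    macro = _bookkeep(macro_pos, macro_a_y, macro_mu, macro_s_y, macro_s_alpha, gcfg, t=t)
    # total free energy: local cells (local beliefs) + local cells (global
    # beliefs) + the fifteen mean-field macros; the explicit macro's own row
    # duplicates its cells' average and is excluded to avoid double counting.
    macro_fe = macro.per_cell_free_energy(gcfg.precisions)
    non_explicit = float(np.sum(np.delete(macro_fe, EXPLICIT)))
    total = float(local.total_f + cell_fe_g + non_explicit)
    return HierarchyState(local=local, macro=macro, t=t, total_f=total)


def init_hierarchy(
    cfg: HierarchyConfig,
    rng_local: Optional[np.random.Generator] = None,
    rng_global: Optional[np.random.Generator] = None,
) -> HierarchyState:
    """Initial condition for both levels, reproducible from the local seed.

    The local ensemble is initialised exactly as in the single-level
    simulation (same seed, same draws).  The global level draws from an
    independent stream: macro positions form a normalised Gaussian cloud at
    ``global_scale`` times the local spread, per-cell global beliefs are
    small perturbations of pluripotency, and the explicit macro's secretion
    and belief are the means over its cells' global actions and beliefs.
    """
    if rng_local is None:
        rng_local = np.random.default_rng(cfg.local.seed)
    if rng_global is None:
        rng_global = _global_rng(cfg)
    local = ensemble_sim.init_ensemble(cfg.local, rng_local)

    gcfg = cfg.global_config
    macro = ensemble_sim.init_ensemble(gcfg, rng_global)

    n = cfg.local.n_cells
    mu_g = rng_global.normal(0.0, cfg.local.init_mu_sd, size=(n, N_TYPES))
    a_y_g = model_core.predict(mu_g, cfg.local.priors).s_y

    macro_mu = macro.mu.copy()
    macro_a_y = macro.a_y.copy()
    macro_mu[EXPLICIT] = mu_g.mean(axis=0)
    macro_a_y[EXPLICIT] = aggregate_up(a_y_g)
    macro_s_alpha = signal_field.all_extracellular(macro.pos, macro_a_y, gcfg.kernel)

    local = _with_globals(local, mu_g, a_y_g)
    eps_g = prediction_errors(
        SensoryState(
            s_y=np.broadcast_to(macro_a_y[EXPLICIT], (n, N_TYPES)),
            s_alpha=np.broadcast_to(macro_s_alpha[EXPLICIT], (n, N_TYPES)),
        ),
        mu_g,
        cfg.local.priors,
    )
    cell_fe_g = float(np.sum(free_energy(eps_g, mu_g, cfg.local.precisions)))
    return _assemble(
        local, macro.pos, macro_a_y, macro_mu, macro_a_y.copy(), macro_s_alpha,
        cfg, t=0.0, cell_fe_g=cell_fe_g,
    )


def _with_globals(local: EnsembleState, mu_g: NDArray, a_y_g: NDArray) -> EnsembleState:
    return EnsembleState(
        pos=local.pos,
        a_y=local.a_y,
        mu=local.mu,
        s_y=local.s_y,
        s_alpha=local.s_alpha,
        eps_y=local.eps_y,
        eps_alpha=local.eps_alpha,
        t=local.t,
        total_f=local.total_f,
        mu_prime=local.mu_prime,
        mu_g=mu_g,
        a_y_g=a_y_g,
    )


def step_hierarchy(
    state: HierarchyState,
    cfg: HierarchyConfig,
    rng_local: np.random.Generator,
    rng_global: np.random.Generator,
) -> HierarchyState:
    """One coupled step of both levels.

    Order: (1) the local ensemble steps exactly as in the single-level
    simulation, consuming only ``rng_local``; (2) the global level is sensed
    with fresh noise from ``rng_global`` — every macro senses its own
    secretion and the kernel-weighted field of the others, and the explicit
    macro's sensation is broadcast identically to all its cells; (3) cells
    update their global beliefs and global secretion actions by the global
    gains; (4) non-explicit macros update as plain level-1 cells at the
    global scale; the explicit macro's secretion is the cells' mean global
    action and its position moves by the cells' mean global chemotactic
    flow.  With ``global_gain = 0`` the local state after the step is
    bit-for-bit the single-level result.
    """
    lcfg, gcfg = cfg.local, cfg.global_config
    priors, prec = lcfg.priors, lcfg.precisions
    n = lcfg.n_cells
    m = cfg.n_ensembles
    dt = lcfg.dt

    # (1) local dynamics (local stream only)
    new_local = ensemble_sim.step(state.local, lcfg, rng_local)

    # (2) global sensing (global stream)
    macro_pos, macro_a_y = signal_field.enact(state.macro.pos, state.macro.a_y)
    macro_a_y[EXPLICIT] = aggregate_up(state.local.a_y_g)
    sd = signal_field.noise_sd(lcfg.noise_log_precision)
    s_y_m = macro_a_y + rng_global.normal(0.0, sd, size=(m, N_TYPES))
    s_alpha_m = signal_field.all_extracellular(macro_pos, macro_a_y, gcfg.kernel)
    s_alpha_m = s_alpha_m + rng_global.normal(0.0, sd, size=(m, N_TYPES))

    # (3) per-cell global updates from the broadcast sensation (identical copies)
    mu_g, a_y_g = state.local.mu_g, state.local.a_y_g
    sense_g = SensoryState(
        s_y=np.broadcast_to(s_y_m[EXPLICIT], (n, N_TYPES)).copy(),
        s_alpha=np.broadcast_to(s_alpha_m[EXPLICIT], (n, N_TYPES)).copy(),
    )
    eps_g = prediction_errors(sense_g, mu_g, priors)
    g_belief = lcfg.belief_gain * cfg.global_gain
    g_secrete = lcfg.secretion_gain * cfg.global_gain
    g_motility = lcfg.motility_gain * cfg.global_gain
    mu_g_new = mu_g + dt * g_belief * belief_flow(eps_g, mu_g, priors, prec)
    a_y_g_new = a_y_g + dt * g_secrete * (-prec.pi_y * eps_g.eps_y)

    # (4) macro updates
    macro_mu = state.macro.mu
    eps_m = prediction_errors(SensoryState(s_y=s_y_m, s_alpha=s_alpha_m), macro_mu, priors)
    mu_m_new = macro_mu + dt * g_belief * belief_flow(eps_m, macro_mu, priors, prec)
    a_y_m_new = macro_a_y + dt * g_secrete * (-prec.pi_y * eps_m.eps_y)
    grads = signal_field.all_position_gradients(macro_pos, macro_a_y, gcfg.kernel)
    flow_x = -np.einsum("kca,kc->ka", grads, prec.pi_alpha * eps_m.eps_alpha)
    pos_m_new = macro_pos + dt * g_motility * flow_x

    # mean-field contract for the explicit macro: secretion and belief are
    # means over its cells; its position moves by the mean cell flow.
    a_y_m_new[EXPLICIT] = aggregate_up(a_y_g_new)
    mu_m_new[EXPLICIT] = mu_g_new.mean(axis=0)
    mean_flow = -grads[EXPLICIT].T @ (prec.pi_alpha * eps_g.eps_alpha.mean(axis=0))
    pos_m_new[EXPLICIT] = macro_pos[EXPLICIT] + dt * g_motility * mean_flow

    local_out = _with_globals(new_local, mu_g_new, a_y_g_new)
    eps_g_out = prediction_errors(sense_g, mu_g_new, priors)
    cell_fe_g = float(np.sum(free_energy(eps_g_out, mu_g_new, prec)))
    return _assemble(
        local_out, pos_m_new, a_y_m_new, mu_m_new, s_y_m, s_alpha_m,
        cfg, t=state.t + dt, cell_fe_g=cell_fe_g,
    )


def run_hierarchy(cfg: HierarchyConfig) -> HierarchyTrajectory:
    """Integrate both levels for ``cfg.local.n_steps`` steps.

    Deterministic given the seed; returns twin trajectories sharing the
    snapshot grid.  In the decoupling limit (``global_gain = 0``) the local
    trajectory equals :func:`blanketsim.ensemble_sim.run` bit for bit.
    """
    rng_local = np.random.default_rng(cfg.local.seed)
    rng_global = _global_rng(cfg)
    state = init_hierarchy(cfg, rng_local, rng_global)
    local_snaps = [state.local]
    macro_snaps = [state.macro]
    stride = cfg.local.snapshot_stride
    for k in range(1, cfg.local.n_steps + 1):
        state = step_hierarchy(state, cfg, rng_local, rng_global)
        if k % stride == 0 or k == cfg.local.n_steps:
            local_snaps.append(state.local)
            macro_snaps.append(state.macro)
    return HierarchyTrajectory(
        local=Trajectory(snapshots=local_snaps, config=cfg.local),
        macro=Trajectory(snapshots=macro_snaps, config=cfg.global_config),
        config=cfg,
    )
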