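"""Single-level ensemble simulation.

Sixteen initially pluripotent cells, each running the generative model of
:mod:`blanketsim.model_core` inside the generative process of
:mod:`blanketsim.signal_field`, are integrated forward with explicit Euler
steps.  Beliefs, secretions and positions all descend the same free-energy
gradients; the ensemble differentiates and arranges itself into an internal
core, an active ring and a sensory periphery without any target morphology
or prescribed type counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.typing import NDArray

from . import model_core, signal_field
from .errors import InvalidInputError, NumericalBlowupError
from .model_core import (
    N_TYPES,
    PredictionError,
    Precisions,
    PriorMatrices,
    SensoryState,
    TypeIndex,
    belief_flow,
    free_energy,
    prediction_errors,
    softmax,
)
from .signal_field import DecayKernel

__all__ = [
    "CellState",
    "EnsembleState",
    "SimConfig",
    "Trajectory",
    "init_ensemble",
    "step",
    "run",
    "differentiation_state",
]


@dataclass(frozen=True)
class SimConfig:
    """Every free parameter of a single-level run.

    The defaults are the calibrated reference configuration: with them the
    reference seeds differentiate into a complete, radially ordered blanket
    within ``n_steps`` Euler steps of size ``dt = 1/32`` (a few seconds of
    wall time).  Sensory noise at ``noise_log_precision = 1`` is load-bearing:
    it lets cells stuck in zero-gradient mixed beliefs diffuse out and stick
    at committed beliefs, where the softmax Jacobian quenches the noise.
    """

    n_cells: int = 16
    priors: PriorMatrices = field(default_factory=PriorMatrices)
    precisions: Precisions = field(default_factory=Precisions)
    kernel: DecayKernel = field(default_factory=DecayKernel)
    noise_log_precision: float = 1.0
    dt: float = 1.0 / 32.0
    n_steps: int = 32768
    snapshot_stride: int = 64
    motility_gain: float = 0.03
    secretion_gain: float = 1.0
    belief_gain: float = 3.0
    generalized_order: int = 1
    mu_damping: float = 1.0
    init_pos_sd: float = 1.2
    init_mu_sd: float = 0.1
    commit_threshold: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise InvalidInputError("n_cells must be positive")
        if self.dt <= 0 or self.n_steps < 0 or self.snapshot_stride <= 0:
            raise InvalidInputError("dt positive, n_steps >= 0, stride positive required")
        for name in ("motility_gain", "secretion_gain", "belief_gain", "init_pos_sd", "init_mu_sd"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")
        if self.generalized_order not in (1, 2):
            raise InvalidInputError("generalized_order must be 1 or 2")
        if not (1.0 / N_TYPES) < self.commit_threshold < 1.0:
            raise InvalidInputError("commit_threshold must lie in (1/3, 1)")


@dataclass(frozen=True)
class CellState:
    """One cell's view of the ensemble state (a convenience projection)."""

    id: int
    pos: NDArray[np.float64]
    a_y: NDArray[np.float64]
    mu: NDArray[np.float64]
    mu_prime: Optional[NDArray[np.float64]]
    last_sense: SensoryState
    last_eps: PredictionError


@dataclass(frozen=True)
class EnsembleState:
    """All cells of one level, stored as stacked arrays.

    ``pos`` (n, 2), ``a_y`` (n, 3) and ``mu`` (n, 3) are simultaneously the
    cells' actions and — by the identity mapping of the generative process —
    the external states of the world.  ``s_y``/``s_alpha``/``eps_y``/
    ``eps_alpha`` record the most recent sensations and the prediction
    errors of the *current* beliefs against them, so ``total_f`` is exactly
    recomputable from the stored fields.  ``mu_g``/``a_y_g`` are attached by
    the hierarchical simulator and stay ``None`` in single-level runs.
    """

    pos: NDArray[np.float64]
    a_y: NDArray[np.float64]
    mu: NDArray[np.float64]
    s_y: NDArray[np.float64]
    s_alpha: NDArray[np.float64]
    eps_y: NDArray[np.float64]
    eps_alpha: NDArray[np.float64]
    t: float
    total_f: float
    mu_prime: Optional[NDArray[np.float64]] = None
    mu_g: Optional[NDArray[np.float64]] = None
    a_y_g: Optional[NDArray[np.float64]] = None

    @property
    def n_cells(self) -> int:
        return self.pos.shape[0]

    @property
    def cells(self) -> list[CellState]:
        return [
            CellState(
                id=i,
                pos=self.pos[i],
                a_y=self.a_y[i],
                mu=self.mu[i],
                mu_prime=None if self.mu_prime is None else self.mu_prime[i],
                last_sense=SensoryState(s_y=self.s_y[i], s_alpha=self.s_alpha[i]),
                last_eps=PredictionError(eps_y=self.eps_y[i], eps_alpha=self.eps_alpha[i]),
            )
            for i in range(self.n_cells)
        ]

    def per_cell_free_energy(self, prec: Precisions) -> NDArray[np.float64]:
        eps = PredictionError(eps_y=self.eps_y, eps_alpha=self.eps_alpha)
        return np.asarray(free_energy(eps, self.mu, prec))


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered snapshots of one level plus the config that produced them."""

    snapshots: list[EnsembleState]
    config: SimConfig

    @property
    def times(self) -> NDArray[np.float64]:
        return np.array([s.t for s in self.snapshots])

    @property
    def free_energies(self) -> NDArray[np.float64]:
        return np.array([s.total_f for s in self.snapshots])


def _bookkeep(
    pos: NDArray,
    a_y: NDArray,
    mu: NDArray,
    s_y: NDArray,
    s_alpha: NDArray,
    cfg: SimConfig,
    t: float,
    mu_prime: Optional[NDArray] = None,
    mu_g: Optional[NDArray] = None,
    a_y_g: Optional[NDArray] = None,
) -> EnsembleState:
    """Assemble a state whose stored errors/free energy match its stored beliefs."""
    eps = prediction_errors(SensoryState(s_y=s_y, s_alpha=s_alpha), mu, cfg.priors)
    f = free_energy(eps, mu, cfg.precisions)
    return EnsembleState(
        pos=pos,
        a_y=a_y,
        mu=mu,
        s_y=s_y,
        s_alpha=s_alpha,
        eps_y=eps.eps_y,
        eps_alpha=eps.eps_alpha,
        t=t,
        total_f=float(np.sum(f)),
        mu_prime=mu_prime,
        mu_g=mu_g,
        a_y_g=a_y_g,
    )


def init_ensemble(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> EnsembleState:
    """Draw the pluripotent initial condition.

    Positions are an isotropic Gaussian cloud around the origin, rescaled to
    a fixed root-mean-square radius of ``init_pos_sd * sqrt(2)`` so that the
    overall density of the initial cloud does not fluctuate between seeds
    (density sets the total sensed signal, and large fluctuations push whole
    ensembles into a single type).  Beliefs are small Gaussian perturbations
    of the uniform expectation; each cell's initial secretion is whatever its
    (near-uniform) belief predicts it should secrete.  Fully reproducible
    from ``cfg.seed`` when no rng is passed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells
    pos = rng.normal(0.0, cfg.init_pos_sd, size=(n, 2))
    if cfg.init_pos_sd > 0 and n > 0:
        rms = np.sqrt(np.mean(np.sum(np.square(pos), axis=1)))
        if rms > 0:
            pos *= cfg.init_pos_sd * np.sqrt(2.0) / rms
    mu = rng.normal(0.0, cfg.init_mu_sd, size=(n, N_TYPES))
    a_y = model_core.predict(mu, cfg.priors).s_y
    s_alpha = signal_field.all_extracellular(pos, a_y, cfg.kernel)
    mu_prime = np.zeros((n, N_TYPES)) if cfg.generalized_order == 2 else None
    return _bookkeep(pos, a_y, mu, a_y.copy(), s_alpha, cfg, t=0.0, mu_prime=mu_prime)


def step(state: EnsembleState, cfg: SimConfig, rng: np.random.Generator) -> EnsembleState:
    """One explicit Euler step of the coupled belief/secretion/position flows.

    Order of operations: actions are enacted (identity), all cells sense the
    resulting world with fresh noise, prediction errors are formed, and the
    three flows are integrated simultaneously from the pre-step state.  With
    all gains zero the state is unchanged apart from refreshed sensations.
    """
    pos, a_y = signal_field.enact(state.pos, state.a_y)
    n = state.n_cells
    prec, priors = cfg.precisions, cfg.priors

    sd = signal_field.noise_sd(cfg.noise_log_precision)
    s_y = a_y + rng.normal(0.0, sd, size=(n, N_TYPES))
    s_alpha = signal_field.all_extracellular(pos, a_y, cfg.kernel) + rng.normal(
        0.0, sd, size=(n, N_TYPES)
    )

    eps = prediction_errors(SensoryState(s_y=s_y, s_alpha=s_alpha), state.mu, priors)

    # Perception: gradient flow on beliefs (optionally with a first
    # generalized order carrying belief velocity).
    flow_mu = cfg.belief_gain * belief_flow(eps, state.mu, priors, prec)
    if cfg.generalized_order == 2:
        mu_prime = state.mu_prime + cfg.dt * (flow_mu - cfg.mu_damping * state.mu_prime)
        mu = state.mu + cfg.dt * state.mu_prime
    else:
        mu_prime = None
        mu = state.mu + cfg.dt * flow_mu

    # Action I: secretion relaxes towards the belief's predicted signature.
    a_y_new = a_y + cfg.dt * cfg.secretion_gain * (-prec.pi_y * eps.eps_y)

    # Action II: chemotaxis down the gradient of extracellular surprise.
    grads = signal_field.all_position_gradients(pos, a_y, cfg.kernel)  # (n, 3, 2)
    flow_x = -np.einsum("ica,ic->ia", grads, prec.pi_alpha * eps.eps_alpha)
    pos_new = pos + cfg.dt * cfg.motility_gain * flow_x

    for name, arr in (("position", pos_new), ("secretion", a_y_new), ("belief", mu)):
        bad = ~np.all(np.isfinite(arr), axis=tuple(range(1, arr.ndim)))
        if np.any(bad):
            raise NumericalBlowupError(
                f"non-finite {name} for cell {int(np.argmax(bad))} at t={state.t + cfg.dt:.4f}"
            )

    return _bookkeep(
        pos_new,
        a_y_new,
        mu,
        s_y,
        s_alpha,
        cfg,
        t=state.t + cfg.dt,
        mu_prime=mu_prime,
        mu_g=state.mu_g,
        a_y_g=state.a_y_g,
    )


def run(cfg: SimConfig) -> Trajectory:
    """Integrate ``cfg.n_steps`` steps, snapshotting every ``snapshot_stride``.

    The initial state and the final state are always included.  The whole
    trajectory is a deterministic function of ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    state = init_ensemble(cfg, rng)
    snapshots = [state]
    for k in range(1, cfg.n_steps + 1):
        state = step(state, cfg, rng)
        if k % cfg.snapshot_stride == 0 or k == cfg.n_steps:
            snapshots.append(state)
    return Trajectory(snapshots=snapshots, config=cfg)


def differentiation_state(
    state: EnsembleState, commit_threshold: float = 0.9
) -> tuple[NDArray[np.bool_], list[Optional[TypeIndex]]]:
    """Which cells have committed to a role, and which role.

    A cell is committed when its largest type expectation exceeds the
    threshold; ties break to the lowest :class:`TypeIndex` (sensory first).
    Returns a boolean array and a per-cell list of roles (``None`` where
    uncommitted).
    """
    if not commit_threshold > 1.0 / N_TYPES:
        raise InvalidInputError("commit threshold must exceed 1/3")
    sigma = softmax(state.mu)
    best = np.argmax(sigma, axis=-1)  # first max wins -> lowest TypeIndex
    committed = sigma[np.arange(state.n_cells), best] > commit_threshold
    types = [TypeIndex(b + 1) if c else None for b, c in zip(best, committed)]
    return committed, types
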