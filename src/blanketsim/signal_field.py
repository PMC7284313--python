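"""Generative process: how actions become external states and sensations.

Cells act by relocating and by secreting three chemical signals.  Actions
map to external states by identity (no lag, no attenuation).  A cell senses
its own secretion directly and everyone else's secretion attenuated by a
spatially decaying kernel — an instantaneous steady-state proxy for signal
diffusion.  Chemotaxis needs the derivative of the sensed extracellular
signal with respect to the cell's own position, computed analytically here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.spatial.distance import cdist

from .errors import InvalidInputError
from .model_core import SensoryState

__all__ = [
    "Position",
    "Secretion",
    "DecayKernel",
    "enact",
    "kernel_weight",
    "extracellular_sensation",
    "all_extracellular",
    "sense",
    "sensation_position_gradient",
    "all_position_gradients",
    "noise_sd",
]

Position = NDArray[np.float64]  # shape (2,)
Secretion = NDArray[np.float64]  # shape (3,)


@dataclass(frozen=True)
class DecayKernel:
    """Spatial attenuation of extracellular signal.

    ``exponential`` gives ``exp(-d / length_scale)``; ``gaussian`` gives
    ``exp(-d^2 / (2 length_scale^2))``.  Both equal 1 at zero distance and
    decay monotonically to 0.
    """

    form: str = "exponential"
    length_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.form not in ("exponential", "gaussian"):
            raise InvalidInputError(f"unknown kernel form: {self.form!r}")
        if self.length_scale <= 0:
            raise InvalidInputError("length_scale must be positive")

    def weight(self, d: ArrayLike) -> NDArray[np.float64]:
        d = np.asarray(d, dtype=float)
        if np.any(d < 0):
            raise InvalidInputError("distance must be non-negative")
        if self.form == "exponential":
            return np.exp(-d / self.length_scale)
        return np.exp(-0.5 * np.square(d / self.length_scale))

    def weight_derivative(self, d: ArrayLike) -> NDArray[np.float64]:
        """d(weight)/dd; strictly non-positive."""
        d = np.asarray(d, dtype=float)
        if self.form == "exponential":
            return -self.weight(d) / self.length_scale
        return -(d / self.length_scale**2) * self.weight(d)


def enact(
    position_actions: ArrayLike, secretion_actions: ArrayLike
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Identity mapping from actions to external states (psi_x, psi_y)."""
    pos = np.asarray(position_actions, dtype=float)
    sec = np.asarray(secretion_actions, dtype=float)
    if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(sec))):
        raise InvalidInputError("actions must be finite")
    return pos.copy(), sec.copy()


def kernel_weight(d: float, k: DecayKernel) -> float:
    """Attenuation factor for a source at distance ``d``; in (0, 1]."""
    return float(k.weight(d))


def _pairwise(positions: NDArray) -> NDArray[np.float64]:
    return cdist(positions, positions)


def all_extracellular(
    positions: ArrayLike, secretions: ArrayLike, k: DecayKernel
) -> NDArray[np.float64]:
    """Extracellular sensation for every cell at once: shape (n, 3).

    Cell i receives ``sum_{j != i} kernel(|x_i - x_j|) y_j``; its own
    secretion is excluded (it is sensed intracellularly instead).
    """
    positions = np.asarray(positions, dtype=float)
    secretions = np.asarray(secretions, dtype=float)
    w = k.weight(_pairwise(positions))
    np.fill_diagonal(w, 0.0)
    return w @ secretions


def extracellular_sensation(
    i: int, positions: ArrayLike, secretions: ArrayLike, k: DecayKernel
) -> NDArray[np.float64]:
    """Kernel-weighted sum of all *other* cells' secretions, for cell ``i``."""
    positions = np.asarray(positions, dtype=float)
    secretions = np.asarray(secretions, dtype=float)
    n = positions.shape[0]
    if not (0 <= i < n):
        raise InvalidInputError(f"cell index {i} out of range for {n} cells")
    if n == 1:
        return np.zeros(3)
    d = np.linalg.norm(positions - positions[i], axis=1)
    w = k.weight(d)
    w[i] = 0.0
    return w @ secretions


def noise_sd(noise_log_precision: float) -> float:
    """Standard deviation of sensory noise with the given log precision."""
    return float(np.exp(-0.5 * noise_log_precision))


def sense(
    i: int,
    positions: ArrayLike,
    secretions: ArrayLike,
    k: DecayKernel,
    noise_log_precision: float,
    rng: np.random.Generator | None = None,
) -> SensoryState:
    """Noisy sensation of cell ``i``: own secretion plus neighbour field.

    Noise is i.i.d. zero-mean Gaussian per channel with standard deviation
    ``exp(-noise_log_precision / 2)``; an infinite log precision (or a
    missing rng) reproduces the noiseless map.
    """
    secretions = np.asarray(secretions, dtype=float)
    s_y = secretions[i].astype(float).copy()
    s_alpha = extracellular_sensation(i, positions, secretions, k)
    sd = noise_sd(noise_log_precision) if np.isfinite(noise_log_precision) else 0.0
    if rng is not None and sd > 0:
        s_y = s_y + rng.normal(0.0, sd, size=3)
        s_alpha = s_alpha + rng.normal(0.0, sd, size=3)
    return SensoryState(s_y=s_y, s_alpha=s_alpha)


def all_position_gradients(
    positions: ArrayLike, secretions: ArrayLike, k: DecayKernel
) -> NDArray[np.float64]:
    """d(s_alpha_i)/d(x_i) for every cell: shape (n, 3, 2).

    Source j contributes ``kernel'(d_ij) * u_ij (x) y_j`` where ``u_ij`` is
    the unit vector from j to i.  Coincident cells contribute zero (the
    symmetric limit), keeping the field singularity-free.
    """
    positions = np.asarray(positions, dtype=float)
    secretions = np.asarray(secretions, dtype=float)
    diff = positions[:, None, :] - positions[None, :, :]  # (n, n, 2), x_i - x_j
    d = np.linalg.norm(diff, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(d[..., None] > 0, diff / np.where(d[..., None] > 0, d[..., None], 1.0), 0.0)
    kp = k.weight_derivative(d)
    np.fill_diagonal(kp, 0.0)
    kp = np.where(d > 0, kp, 0.0)
    # grad[i, c, a] = sum_j kp[i, j] * unit[i, j, a] * y[j, c]
    return np.einsum("ij,ija,jc->ica", kp, unit, secretions)


def sensation_position_gradient(
    i: int, positions: ArrayLike, secretions: ArrayLike, k: DecayKernel
) -> NDArray[np.float64]:
    """Analytic derivative of cell ``i``'s extracellular sensation w.r.t. its own position."""
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if not (0 <= i < n):
        raise InvalidInputError(f"cell index {i} out of range for {n} cells")
    return all_position_gradients(positions, secretions, k)[i]
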