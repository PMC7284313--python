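"""Generative model of a single cell.

Each simulated cell entertains a belief about which of three roles it plays
in a Markov blanket — *sensory*, *active* or *internal* — and predicts, from
that belief, which chemical signals it should secrete and sense.  Perception
(belief updating), secretion and movement are all gradient flows on a single
variational free energy, which under the Laplace (quadratic) assumption is a
precision-weighted sum of squared prediction errors plus a Gaussian prior
over the belief itself.

Project-wide type ordering
--------------------------
Every length-3 vector in this package is indexed in the fixed order
``(sensory, active, internal)``.  In that ordering the extracellular prior
matrix has the band support pattern ``[[1,1,0],[1,1,1],[0,1,1]]``: sensory
cells exchange signal with active cells, active cells with both neighbours,
and sensory and internal cells never couple directly — the conditional
independence that defines a Markov blanket.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .errors import InvalidInputError

__all__ = [
    "TypeIndex",
    "N_TYPES",
    "PriorMatrices",
    "Precisions",
    "SensoryState",
    "PredictionError",
    "softmax",
    "softmax_jacobian",
    "predict",
    "prediction_errors",
    "free_energy",
    "belief_flow",
]

N_TYPES = 3


class TypeIndex(IntEnum):
    """The three blanket roles, in the fixed project-wide order.

    ``index`` (value - 1) is the position of the role in every length-3
    vector and in the rows/columns of the prior matrices.
    """

    SENSORY = 1
    ACTIVE = 2
    INTERNAL = 3

    @property
    def index(self) -> int:
        return self.value - 1


def _default_p_y() -> NDArray[np.float64]:
    # Each type secretes two units of its own signal.  The factor 2 (shared
    # with p_alpha) raises residual belief drive above the fixed sensory
    # noise floor; see docs/methods.md, "Calibration of the prior matrices".
    return 2.0 * np.eye(N_TYPES)


def _default_p_alpha() -> NDArray[np.float64]:
    # (sensory, active, internal) ordering: sensory<->active, active<->all,
    # internal<->active; no direct sensory<->internal coupling.  The entries
    # are calibrated, not symmetric: each column is an expected sensation
    # profile chosen (by a maximin stability-margin optimisation over the
    # empirically converged blanket geometry) so that all three committed
    # roles are simultaneously stable and a pluripotent cell is allocated to
    # the role matching its local signal density.  A symmetric matrix has an
    # exact sensory<->internal relabelling symmetry and provably cannot
    # stabilise the blanket; see docs/methods.md.
    return np.array(
        [
            [0.01, 0.01, 0.0],
            [0.850929670855348, 2.6575826437083627, 3.0739853446781837],
            [0.0, 0.887405149747428, 0.8474051497474271],
        ]
    )


@dataclass(frozen=True)
class PriorMatrices:
    """Fixed ("genetic") prior mappings from cell type to predicted signal.

    ``p_y`` maps the type expectation to the predicted *intracellular*
    signal (what the cell itself secretes): each type secretes one unique
    signal, so ``p_y`` is a positive multiple of the identity.  ``p_alpha``
    maps the type expectation to the predicted *extracellular* sensation and
    carries the blanket's dependency structure.  ``scale`` is a single
    calibration constant multiplying ``p_alpha``; it sets how much total
    extracellular signal a cell expects to receive from its neighbours.
    """

    p_y: NDArray[np.float64] = field(default_factory=_default_p_y)
    p_alpha: NDArray[np.float64] = field(default_factory=_default_p_alpha)
    scale: float = 1.0

    def __post_init__(self) -> None:
        p_y = np.asarray(self.p_y, dtype=float)
        p_alpha = np.asarray(self.p_alpha, dtype=float)
        if p_y.shape != (N_TYPES, N_TYPES) or p_alpha.shape != (N_TYPES, N_TYPES):
            raise InvalidInputError("prior matrices must be 3x3")
        if np.any(p_y < 0) or np.any(p_alpha < 0):
            raise InvalidInputError("prior matrices must be non-negative")
        s, i = TypeIndex.SENSORY.index, TypeIndex.INTERNAL.index
        if p_alpha[s, i] != 0.0 or p_alpha[i, s] != 0.0:
            raise InvalidInputError(
                "p_alpha must carry no direct sensory-internal coupling"
            )
        if self.scale <= 0:
            raise InvalidInputError("scale must be positive")
        object.__setattr__(self, "p_y", p_y)
        object.__setattr__(self, "p_alpha", p_alpha)


@dataclass(frozen=True)
class Precisions:
    """Model precisions (inverse variances) weighting the free energy.

    ``pi_y`` and ``pi_alpha`` weight the intracellular and extracellular
    prediction errors; ``pi_prior`` is the precision of the zero-mean
    Gaussian prior that shrinks beliefs towards pluripotency (uniform type
    expectation).  These are the *model's* confidence settings and are
    deliberately decoupled from the generative process's sensory-noise
    precision, which only sets the noise amplitude on sensations.  The
    default ``pi_prior`` is numerically negligible, making commitment
    effectively absorbing: a committed belief has a near-zero softmax
    Jacobian, so neither noise nor the prior can pull it back to
    pluripotency.  Raising ``pi_prior`` makes commitment leaky.
    """

    pi_y: float = float(np.exp(2.0))
    pi_alpha: float = float(np.exp(2.0))
    pi_prior: float = float(np.exp(-16.0))

    def __post_init__(self) -> None:
        if not (np.isfinite(self.pi_y) and np.isfinite(self.pi_alpha) and np.isfinite(self.pi_prior)):
            raise InvalidInputError("precisions must be finite")
        if self.pi_y <= 0 or self.pi_alpha <= 0:
            raise InvalidInputError("sensory precisions must be positive")
        if self.pi_prior < 0:
            raise InvalidInputError("prior precision must be non-negative")


@dataclass(frozen=True)
class SensoryState:
    """Sensed intracellular (``s_y``) and extracellular (``s_alpha``) signals."""

    s_y: NDArray[np.float64]
    s_alpha: NDArray[np.float64]


@dataclass(frozen=True)
class PredictionError:
    """Sensation minus prediction, per channel."""

    eps_y: NDArray[np.float64]
    eps_alpha: NDArray[np.float64]


def _check_finite(name: str, a: NDArray) -> NDArray[np.float64]:
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)):
        raise InvalidInputError(f"{name} must be finite")
    return a


def softmax(mu: ArrayLike) -> NDArray[np.float64]:
    """Type expectation: softmax over the belief's last axis.

    Shift-invariant and numerically stable for entries up to +/-700.
    Accepts batched input of shape ``(..., 3)``.
    """
    mu = _check_finite("belief", np.asarray(mu))
    z = mu - np.max(mu, axis=-1, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=-1, keepdims=True)


def softmax_jacobian(mu: ArrayLike) -> NDArray[np.float64]:
    """Jacobian of the softmax: ``diag(sigma) - sigma sigma^T``.

    Symmetric, rows sum to zero (shift invariance).  Batched over leading
    axes: returns shape ``(..., 3, 3)``.
    """
    s = softmax(mu)
    return s[..., :, None] * np.eye(N_TYPES) - s[..., :, None] * s[..., None, :]


def predict(mu: ArrayLike, priors: PriorMatrices) -> SensoryState:
    """Predicted sensations given a belief: ``g(mu) = [p_y; scale*p_alpha] sigma(mu)``."""
    s = softmax(mu)
    s_y = s @ priors.p_y.T
    s_alpha = priors.scale * (s @ priors.p_alpha.T)
    return SensoryState(s_y=s_y, s_alpha=s_alpha)


def prediction_errors(
    s: SensoryState, mu: ArrayLike, priors: PriorMatrices
) -> PredictionError:
    """Prediction error ``eps = s - g(mu)``, componentwise."""
    pred = predict(mu, priors)
    return PredictionError(
        eps_y=np.asarray(s.s_y, dtype=float) - pred.s_y,
        eps_alpha=np.asarray(s.s_alpha, dtype=float) - pred.s_alpha,
    )


def free_energy(
    eps: PredictionError, mu: ArrayLike, prec: Precisions
) -> NDArray[np.float64] | float:
    """Laplace-form variational free energy (additive constants dropped).

    ``F = 1/2 pi_y |eps_y|^2 + 1/2 pi_alpha |eps_alpha|^2 + 1/2 pi_prior |mu|^2``

    Non-negative; zero only with vanishing errors and (no prior shrinkage or
    a pluripotent belief).  Batched over leading axes.
    """
    mu = np.asarray(mu, dtype=float)
    f = (
        0.5 * prec.pi_y * np.sum(np.square(eps.eps_y), axis=-1)
        + 0.5 * prec.pi_alpha * np.sum(np.square(eps.eps_alpha), axis=-1)
        + 0.5 * prec.pi_prior * np.sum(np.square(mu), axis=-1)
    )
    return float(f) if np.ndim(f) == 0 else f


def belief_flow(
    eps: PredictionError,
    mu: ArrayLike,
    priors: PriorMatrices,
    prec: Precisions,
) -> NDArray[np.float64]:
    """Negative free-energy gradient with respect to the belief.

    ``-dF/dmu = J_sigma(mu)^T (p_y^T pi_y eps_y + scale p_alpha^T pi_alpha
    eps_alpha) - pi_prior mu``, where ``J_sigma`` is the (symmetric) softmax
    Jacobian.  Sensations are treated as fixed, so this is the perceptual
    part of the descent: beliefs move to explain what is currently sensed.
    Batched over leading axes.
    """
    mu = _check_finite("belief", np.asarray(mu))
    eps_y = np.asarray(eps.eps_y, dtype=float)
    eps_alpha = np.asarray(eps.eps_alpha, dtype=float)
    # p^T pi eps, batched:  (..., 3) @ (3, 3) contracts the channel axis.
    drive = prec.pi_y * (eps_y @ priors.p_y) + priors.scale * prec.pi_alpha * (
        eps_alpha @ priors.p_alpha
    )
    s = softmax(mu)
    # J_sigma drive = sigma*drive - sigma (sigma . drive); J is symmetric.
    jd = s * drive - s * np.sum(s * drive, axis=-1, keepdims=True)
    return jd - prec.pi_prior * mu
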