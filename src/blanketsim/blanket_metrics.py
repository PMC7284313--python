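"""Quantitative checks that a configuration really is a Markov blanket.

A converged ensemble should show (i) full differentiation into the three
roles, (ii) the onion morphology — internal core, active ring, sensory
periphery — measured by per-type mean distance to the committed centroid,
(iii) negligible *direct* internal-sensory coupling relative to the
blanket-mediated internal-active coupling, measured by a kernel-weight
ratio, and (iv) free-energy descent over the run.  All metrics are invariant
under rigid motions and cell permutations, and every threshold is surfaced
in the report rather than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .ensemble_sim import EnsembleState, SimConfig, Trajectory, differentiation_state
from .errors import InvalidInputError, MetricUndefinedError
from .model_core import N_TYPES, TypeIndex, softmax
from .signal_field import DecayKernel

__all__ = [
    "BlanketReport",
    "radial_ordering",
    "independence_ratio",
    "free_energy_descent",
    "commit_times",
    "report",
]

NOT_CONVERGED = float("inf")


@dataclass(frozen=True)
class BlanketReport:
    """Aggregated blanket diagnostics for one configuration.

    ``type_counts`` is ordered (sensory, active, internal) like every other
    length-3 vector in the package, and counts only committed cells.
    ``radial_means`` may contain NaN where a type is absent.  ``passes`` is
    the conjunction of: all cells committed, all three types present, radial
    ordering internal < active < sensory, and ``independence_ratio`` below
    the (reported) threshold.
    """

    committed_count: int
    type_counts: tuple[int, int, int]
    radial_means: tuple[float, float, float]
    radial_ordered: bool
    independence_ratio: float
    independence_threshold: float
    commit_threshold: float
    passes: bool

    def to_dict(self) -> dict:
        return {
            "committed_count": self.committed_count,
            "type_counts": list(self.type_counts),
            "radial_means": list(self.radial_means),
            "radial_ordered": self.radial_ordered,
            "independence_ratio": self.independence_ratio,
            "independence_threshold": self.independence_threshold,
            "commit_threshold": self.commit_threshold,
            "passes": self.passes,
        }


def _labels_array(labels: Sequence[Optional[TypeIndex]] | ArrayLike) -> NDArray[np.int_]:
    """Normalise labels to an int array: -1 uncommitted, else TypeIndex.index."""
    out = []
    for lab in labels:  # type: ignore[union-attr]
        if lab is None:
            out.append(-1)
        elif isinstance(lab, TypeIndex):
            out.append(lab.index)
        else:
            k = int(lab)
            if not 0 <= k < N_TYPES:
                raise InvalidInputError(f"label {lab!r} is not a valid type index")
            out.append(k)
    return np.array(out, dtype=int)


def _require_all_types(lab: NDArray[np.int_]) -> None:
    missing = [TypeIndex(k + 1).name for k in range(N_TYPES) if not np.any(lab == k)]
    if missing:
        raise MetricUndefinedError(
            f"metric undefined: no committed cells of type(s) {', '.join(missing)}"
        )


def radial_ordering(
    positions: ArrayLike, labels: Sequence[Optional[TypeIndex]] | ArrayLike
) -> tuple[NDArray[np.float64], bool]:
    """Per-type mean distance to the committed centroid, and the order flag.

    The centroid is the mean position of committed cells only, so straggling
    uncommitted cells cannot drag the reference point.  Ordered means
    internal < active < sensory (strictly).  Raises
    :class:`MetricUndefinedError` when any type has no committed cell.
    """
    pos = np.asarray(positions, dtype=float)
    lab = _labels_array(labels)
    if pos.shape[0] != lab.shape[0]:
        raise InvalidInputError("positions and labels must have equal length")
    _require_all_types(lab)
    centroid = pos[lab >= 0].mean(axis=0)
    r = np.linalg.norm(pos - centroid, axis=1)
    means = np.array([float(r[lab == k].mean()) for k in range(N_TYPES)])
    s, a, i = (TypeIndex.SENSORY.index, TypeIndex.ACTIVE.index, TypeIndex.INTERNAL.index)
    ordered = bool(means[i] < means[a] < means[s])
    return means, ordered


def independence_ratio(
    positions: ArrayLike,
    labels: Sequence[Optional[TypeIndex]] | ArrayLike,
    kernel: DecayKernel,
) -> float:
    """Direct internal-sensory coupling relative to internal-active coupling.

    Under spatially decaying signalling the coupling magnitude between two
    cells *is* the kernel weight of their distance, so the ratio of mean
    kernel weights over internal-sensory pairs to internal-active pairs
    measures how well the active ring insulates the core.  Well below 1
    means internal cells talk to sensory cells only through the blanket.
    """
    pos = np.asarray(positions, dtype=float)
    lab = _labels_array(labels)
    if pos.shape[0] != lab.shape[0]:
        raise InvalidInputError("positions and labels must have equal length")
    _require_all_types(lab)
    s, a, i = (TypeIndex.SENSORY.index, TypeIndex.ACTIVE.index, TypeIndex.INTERNAL.index)

    def mean_weight(ka: int, kb: int) -> float:
        pa, pb = pos[lab == ka], pos[lab == kb]
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
        return float(np.mean(kernel.weight(d)))

    return mean_weight(i, s) / mean_weight(i, a)


def free_energy_descent(
    trajectory: Trajectory, window: int = 100
) -> tuple[float, float, bool]:
    """Windowed free-energy descent check.

    The total-F trace is smoothed with a trailing moving mean of ``window``
    snapshots that expands from the first snapshot (the window never reaches
    before the series start), so the smoothed series keeps the true initial
    value and its range reflects the actual descent rather than only the
    converged noise envelope.  Descent holds iff the final windowed mean is
    below the initial one and the windowed series never rises by more than
    1% of its own range (sensory noise makes strict monotonicity too strong
    a demand).  The default window keeps the smoothed noise excursions of
    the reference configuration well inside that tolerance.
    """
    if window <= 0:
        raise InvalidInputError("window must be positive")
    f = trajectory.free_energies
    if f.size < 2:
        raise InvalidInputError("need at least two snapshots")
    # trailing mean with expanding start: smooth[i] = mean(f[max(0, i-w+1) : i+1])
    c = np.concatenate([[0.0], np.cumsum(f)])
    idx = np.arange(1, f.size + 1)
    lo = np.maximum(0, idx - window)
    smooth = (c[idx] - c[lo]) / (idx - lo)
    initial, final = float(smooth[0]), float(smooth[-1])
    rng = float(smooth.max() - smooth.min())
    tol = 0.01 * rng
    rises = np.diff(smooth)
    descent = bool(final < initial and np.all(rises <= tol))
    return initial, final, descent


def commit_times(
    trajectory: Trajectory, threshold: float = 0.9
) -> NDArray[np.float64]:
    """Per-cell time of the last crossing into commitment that is never left.

    Scans each cell's expectation trace: the reported time is the earliest
    snapshot from which the cell stays committed (same type, above
    threshold) until the end of the trajectory.  Cells not committed at the
    final snapshot get ``inf`` (not converged).
    """
    if not threshold > 1.0 / N_TYPES:
        raise InvalidInputError("threshold must exceed 1/3")
    snaps = trajectory.snapshots
    times = trajectory.times
    sigma = np.stack([softmax(s.mu) for s in snaps])  # (T, n, 3)
    best = np.argmax(sigma, axis=-1)
    committed = np.take_along_axis(sigma, best[..., None], axis=-1)[..., 0] > threshold
    n = sigma.shape[1]
    out = np.full(n, NOT_CONVERGED)
    for c in range(n):
        if not committed[-1, c]:
            continue
        final_type = best[-1, c]
        ok = committed[:, c] & (best[:, c] == final_type)
        # walk back from the end through the unbroken committed suffix
        t_idx = len(snaps) - 1
        while t_idx > 0 and ok[t_idx - 1]:
            t_idx -= 1
        out[c] = times[t_idx]
    return out


def report(
    state_or_traj: EnsembleState | Trajectory,
    cfg: SimConfig,
    independence_threshold: float = 0.5,
) -> BlanketReport:
    """Full blanket report for a final state (or a trajectory's final state)."""
    state = (
        state_or_traj.snapshots[-1]
        if isinstance(state_or_traj, Trajectory)
        else state_or_traj
    )
    committed, types = differentiation_state(state, cfg.commit_threshold)
    lab = _labels_array(types)
    counts = tuple(int(np.sum(lab == k)) for k in range(N_TYPES))
    try:
        means, ordered = radial_ordering(state.pos, types)
        ratio = independence_ratio(state.pos, types, cfg.kernel)
        defined = True
    except MetricUndefinedError:
        means = np.full(N_TYPES, np.nan)
        ordered = False
        ratio = float("nan")
        defined = False
    passes = bool(
        defined
        and committed.all()
        and all(c > 0 for c in counts)
        and ordered
        and ratio < independence_threshold
    )
    return BlanketReport(
        committed_count=int(committed.sum()),
        type_counts=counts,  # type: ignore[arg-type]
        radial_means=tuple(float(m) for m in means),  # type: ignore[arg-type]
        radial_ordered=bool(ordered),
        independence_ratio=float(ratio),
        independence_threshold=float(independence_threshold),
        commit_threshold=float(cfg.commit_threshold),
        passes=passes,
    )
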