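"""Figure rendering: scatter frames coloured by type expectation.

Colour convention (fixed project-wide, matching the type ordering): sensory
is blue, active is green, internal is red.  A cell's colour is its type
expectation mixed as RGB, so committed cells are saturated and pluripotent
cells render as a grey-ish mixture.  Hierarchical renders draw the macro
ensemble as large circles with the explicit ensemble's cells inset.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .ensemble_sim import EnsembleState, Trajectory
from .hierarchy_sim import EXPLICIT, HierarchyTrajectory
from .model_core import TypeIndex, softmax

__all__ = ["expectation_colors", "render_state", "render", "render_animation"]


def expectation_colors(mu: np.ndarray) -> np.ndarray:
    """RGB colours from beliefs: red=internal, green=active, blue=sensory."""
    sigma = softmax(mu)
    s, a, i = (TypeIndex.SENSORY.index, TypeIndex.ACTIVE.index, TypeIndex.INTERNAL.index)
    return np.stack([sigma[:, i], sigma[:, a], sigma[:, s]], axis=1)


def render_state(
    state: EnsembleState,
    path: str | Path,
    title: Optional[str] = None,
    macro_state: Optional[EnsembleState] = None,
) -> Path:
    """One PNG frame; with ``macro_state`` draws the hierarchical layout."""
    fig, ax = plt.subplots(figsize=(5, 5))
    if macro_state is not None:
        ax.scatter(
            macro_state.pos[:, 0],
            macro_state.pos[:, 1],
            s=900,
            c=expectation_colors(macro_state.mu),
            alpha=0.35,
            edgecolors="k",
            linewidths=0.5,
        )
        # inset the explicit ensemble's cells around their macro's position
        anchor = macro_state.pos[EXPLICIT]
        cell_pos = state.pos - state.pos.mean(axis=0) + anchor
        ax.scatter(
            cell_pos[:, 0], cell_pos[:, 1], s=25, c=expectation_colors(state.mu),
            edgecolors="k", linewidths=0.2,
        )
    else:
        ax.scatter(
            state.pos[:, 0], state.pos[:, 1], s=120, c=expectation_colors(state.mu),
            edgecolors="k", linewidths=0.4,
        )
    ax.set_aspect("equal")
    ax.set_title(title or f"t = {state.t:.2f}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


def render(
    traj: Trajectory | HierarchyTrajectory,
    out_dir: str | Path,
    max_frames: int = 16,
) -> list[Path]:
    """PNG frames evenly sampled along the trajectory (at most ``max_frames``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hier = isinstance(traj, HierarchyTrajectory)
    snaps = traj.local.snapshots if hier else traj.snapshots
    macro = traj.macro.snapshots if hier else None
    idx = np.unique(np.linspace(0, len(snaps) - 1, min(max_frames, len(snaps))).astype(int))
    paths = []
    for j, k in enumerate(idx):
        paths.append(
            render_state(
                snaps[k],
                out / f"frame_{j:04d}.png",
                macro_state=None if macro is None else macro[k],
            )
        )
    return paths


def render_animation(
    traj: Trajectory | HierarchyTrajectory, path: str | Path, max_frames: int = 64
) -> Path:
    """Assemble an animated GIF from sampled frames."""
    from matplotlib.animation import FuncAnimation, PillowWriter

    hier = isinstance(traj, HierarchyTrajectory)
    snaps = traj.local.snapshots if hier else traj.snapshots
    macro = traj.macro.snapshots if hier else None
    idx = np.unique(np.linspace(0, len(snaps) - 1, min(max_frames, len(snaps))).astype(int))

    fig, ax = plt.subplots(figsize=(5, 5))
    all_pos = np.concatenate(
        [(macro or snaps)[k].pos for k in idx]  # type: ignore[index]
    )
    lim = 1.1 * np.max(np.abs(all_pos)) + 1.0

    def draw(frame: int) -> None:
        ax.clear()
        k = idx[frame]
        if macro is not None:
            ax.scatter(
                macro[k].pos[:, 0], macro[k].pos[:, 1], s=900,
                c=expectation_colors(macro[k].mu), alpha=0.35,
                edgecolors="k", linewidths=0.5,
            )
            anchor = macro[k].pos[EXPLICIT]
            cp = snaps[k].pos - snaps[k].pos.mean(axis=0) + anchor
            ax.scatter(cp[:, 0], cp[:, 1], s=25, c=expectation_colors(snaps[k].mu))
        else:
            ax.scatter(
                snaps[k].pos[:, 0], snaps[k].pos[:, 1], s=120,
                c=expectation_colors(snaps[k].mu), edgecolors="k", linewidths=0.4,
            )
        ax.set_xlim(-lim, lim)
        ax.set_ylim(-lim, lim)
        ax.set_aspect("equal")
        ax.set_title(f"t = {snaps[k].t:.2f}")

    anim = FuncAnimation(fig, draw, frames=len(idx))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    anim.save(path, writer=PillowWriter(fps=8))
    plt.close(fig)
    return path
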