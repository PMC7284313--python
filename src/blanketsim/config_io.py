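"""Configuration files, trajectory tables, reports and fixtures.

The configuration is a YAML document with sections ``model``, ``world``,
``integration``, ``hierarchy``, ``metrics`` and ``output``.  Every field has
a documented default equal to the reference configuration, so an empty file
is a valid config; unknown keys are an error (silent typos in parameter
names would otherwise silently change an experiment).  The loaded config is
echoed verbatim-equivalent (fully resolved) into the output directory as
JSON for provenance.

Trajectories are written long-format: one CSV row per cell per snapshot per
level, with positions, secretions, beliefs, type expectations and per-cell
free energy.  Numbers are written with ``repr`` fidelity, so a read-back
reproduces every field exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import model_core
from .ensemble_sim import EnsembleState, SimConfig, Trajectory, _bookkeep
from .errors import ConfigError, InvalidInputError
from .hierarchy_sim import HierarchyConfig, HierarchyTrajectory
from .model_core import N_TYPES, Precisions, PriorMatrices, TypeIndex, softmax
from .signal_field import DecayKernel, all_extracellular

__all__ = [
    "LoadedConfig",
    "load_config",
    "config_to_dict",
    "echo_config",
    "write_trajectory",
    "write_hierarchy_trajectory",
    "read_trajectory",
    "trajectory_frame",
    "make_fixture",
    "FIXTURE_KINDS",
]

TRAJECTORY_COLUMNS = [
    "time",
    "level",
    "cell",
    "x",
    "y",
    "secretion_1",
    "secretion_2",
    "secretion_3",
    "belief_1",
    "belief_2",
    "belief_3",
    "expectation_1",
    "expectation_2",
    "expectation_3",
    "free_energy",
]

FIXTURE_KINDS = ("converged_level1", "shuffled", "converged_hierarchy")


@dataclass(frozen=True)
class LoadedConfig:
    """A fully resolved configuration: simulation, optional hierarchy, extras."""

    sim: SimConfig
    hierarchy: Optional[HierarchyConfig]
    independence_threshold: float
    fe_window: int
    output_dir: Optional[str]
    render: bool
    animate: bool


def _require_mapping(value: Any, where: str) -> dict:
    if value is None:
        return {}
    if not isinstance(value, dict):
        raise ConfigError(f"section {where!r} must be a mapping, got {type(value).__name__}")
    return value


def _pop(section: dict, key: str, default: Any, where: str, typ: type | tuple) -> Any:
    value = section.pop(key, default)
    if value is None:
        return default
    if typ is float and isinstance(value, int) and not isinstance(value, bool):
        value = float(value)
    if not isinstance(value, typ) or isinstance(value, bool) and typ is not bool:
        raise ConfigError(f"key {where}.{key} must be {typ}, got {value!r}")
    return value


def _pop_matrix(section: dict, key: str, default: np.ndarray, where: str) -> np.ndarray:
    value = section.pop(key, None)
    if value is None:
        return default
    arr = np.asarray(value, dtype=float)
    if arr.shape != (N_TYPES, N_TYPES):
        raise ConfigError(f"key {where}.{key} must be a 3x3 matrix")
    return arr


def _check_empty(section: dict, where: str) -> None:
    if section:
        key = next(iter(section))
        raise ConfigError(f"unknown key {where}.{key}")


def load_config(path: str | Path | None = None, seed: Optional[int] = None) -> LoadedConfig:
    """Load and validate a YAML config; ``None`` or an empty file gives defaults.

    ``seed`` (e.g. from the command line) overrides the config's seed.
    Raises :class:`ConfigError` naming the offending key on unknown keys or
    wrong types.
    """
    doc: Any = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        doc = yaml.safe_load(p.read_text()) or {}
    doc = _require_mapping(doc, "<root>")
    doc = dict(doc)

    defaults = SimConfig()
    dpri, dprec, dker = defaults.priors, defaults.precisions, defaults.kernel

    model = dict(_require_mapping(doc.pop("model", None), "model"))
    p_y = _pop_matrix(model, "p_y", dpri.p_y, "model")
    p_alpha = _pop_matrix(model, "p_alpha", dpri.p_alpha, "model")
    scale = _pop(model, "scale", dpri.scale, "model", float)
    pi_y = _pop(model, "pi_y", dprec.pi_y, "model", float)
    pi_alpha = _pop(model, "pi_alpha", dprec.pi_alpha, "model", float)
    pi_prior = _pop(model, "pi_prior", dprec.pi_prior, "model", float)
    _check_empty(model, "model")

    world = dict(_require_mapping(doc.pop("world", None), "world"))
    n_cells = _pop(world, "n_cells", defaults.n_cells, "world", int)
    kernel_form = _pop(world, "kernel_form", dker.form, "world", str)
    kernel_ls = _pop(world, "kernel_length_scale", dker.length_scale, "world", float)
    nlp = _pop(world, "noise_log_precision", defaults.noise_log_precision, "world", float)
    init_pos_sd = _pop(world, "init_pos_sd", defaults.init_pos_sd, "world", float)
    init_mu_sd = _pop(world, "init_mu_sd", defaults.init_mu_sd, "world", float)
    _check_empty(world, "world")

    integ = dict(_require_mapping(doc.pop("integration", None), "integration"))
    dt = _pop(integ, "dt", defaults.dt, "integration", float)
    n_steps = _pop(integ, "n_steps", defaults.n_steps, "integration", int)
    stride = _pop(integ, "snapshot_stride", defaults.snapshot_stride, "integration", int)
    motility = _pop(integ, "motility_gain", defaults.motility_gain, "integration", float)
    secretion = _pop(integ, "secretion_gain", defaults.secretion_gain, "integration", float)
    belief = _pop(integ, "belief_gain", defaults.belief_gain, "integration", float)
    order = _pop(integ, "generalized_order", defaults.generalized_order, "integration", int)
    damping = _pop(integ, "mu_damping", defaults.mu_damping, "integration", float)
    cfg_seed = _pop(integ, "seed", defaults.seed, "integration", int)
    _check_empty(integ, "integration")

    metrics = dict(_require_mapping(doc.pop("metrics", None), "metrics"))
    commit = _pop(metrics, "commit_threshold", defaults.commit_threshold, "metrics", float)
    indep = _pop(metrics, "independence_threshold", 0.5, "metrics", float)
    fe_window = _pop(metrics, "fe_window", 10, "metrics", int)
    _check_empty(metrics, "metrics")

    output = dict(_require_mapping(doc.pop("output", None), "output"))
    out_dir = output.pop("directory", None)
    if out_dir is not None and not isinstance(out_dir, str):
        raise ConfigError("key output.directory must be a string")
    render = _pop(output, "render", False, "output", bool)
    animate = _pop(output, "animate", False, "output", bool)
    _check_empty(output, "output")

    hierarchy_doc = doc.pop("hierarchy", None)
    _check_empty(doc, "<root>")

    try:
        sim = SimConfig(
            n_cells=n_cells,
            priors=PriorMatrices(p_y=p_y, p_alpha=p_alpha, scale=scale),
            precisions=Precisions(pi_y=pi_y, pi_alpha=pi_alpha, pi_prior=pi_prior),
            kernel=DecayKernel(form=kernel_form, length_scale=kernel_ls),
            noise_log_precision=nlp,
            dt=dt,
            n_steps=n_steps,
            snapshot_stride=stride,
            motility_gain=motility,
            secretion_gain=secretion,
            belief_gain=belief,
            generalized_order=order,
            mu_damping=damping,
            init_pos_sd=init_pos_sd,
            init_mu_sd=init_mu_sd,
            commit_threshold=commit,
            seed=cfg_seed if seed is None else int(seed),
        )
    except InvalidInputError as exc:
        raise ConfigError(str(exc)) from exc

    hierarchy = None
    if hierarchy_doc is not None:
        h = dict(_require_mapping(hierarchy_doc, "hierarchy"))
        n_ens = _pop(h, "n_ensembles", 16, "hierarchy", int)
        gscale = _pop(h, "global_scale", 4.0, "hierarchy", float)
        ggain = _pop(h, "global_gain", 0.25, "hierarchy", float)
        _check_empty(h, "hierarchy")
        try:
            hierarchy = HierarchyConfig(
                local=sim, n_ensembles=n_ens, global_scale=gscale, global_gain=ggain
            )
        except InvalidInputError as exc:
            raise ConfigError(str(exc)) from exc

    return LoadedConfig(
        sim=sim,
        hierarchy=hierarchy,
        independence_threshold=indep,
        fe_window=fe_window,
        output_dir=out_dir,
        render=render,
        animate=animate,
    )


def config_to_dict(loaded: LoadedConfig) -> dict:
    """Fully resolved configuration as plain JSON-serialisable data."""
    sim = loaded.sim
    out: dict[str, Any] = {
        "model": {
            "p_y": sim.priors.p_y.tolist(),
            "p_alpha": sim.priors.p_alpha.tolist(),
            "scale": sim.priors.scale,
            "pi_y": sim.precisions.pi_y,
            "pi_alpha": sim.precisions.pi_alpha,
            "pi_prior": sim.precisions.pi_prior,
        },
        "world": {
            "n_cells": sim.n_cells,
            "kernel_form": sim.kernel.form,
            "kernel_length_scale": sim.kernel.length_scale,
            "noise_log_precision": sim.noise_log_precision,
            "init_pos_sd": sim.init_pos_sd,
            "init_mu_sd": sim.init_mu_sd,
        },
        "integration": {
            "dt": sim.dt,
            "n_steps": sim.n_steps,
            "snapshot_stride": sim.snapshot_stride,
            "motility_gain": sim.motility_gain,
            "secretion_gain": sim.secretion_gain,
            "belief_gain": sim.belief_gain,
            "generalized_order": sim.generalized_order,
            "mu_damping": sim.mu_damping,
            "seed": sim.seed,
        },
        "metrics": {
            "commit_threshold": sim.commit_threshold,
            "independence_threshold": loaded.independence_threshold,
            "fe_window": loaded.fe_window,
        },
        "output": {
            "directory": loaded.output_dir,
            "render": loaded.render,
            "animate": loaded.animate,
        },
    }
    if loaded.hierarchy is not None:
        out["hierarchy"] = {
            "n_ensembles": loaded.hierarchy.n_ensembles,
            "global_scale": loaded.hierarchy.global_scale,
            "global_gain": loaded.hierarchy.global_gain,
        }
    return out


def echo_config(loaded: LoadedConfig, out_dir: str | Path) -> Path:
    """Write the resolved configuration into the output directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "config.json"
    path.write_text(json.dumps(config_to_dict(loaded), indent=2) + "\n")
    return path


def _frame_for(traj: Trajectory, level: str) -> pd.DataFrame:
    rows = []
    for snap in traj.snapshots:
        sigma = softmax(snap.mu)
        fe = snap.per_cell_free_energy(traj.config.precisions)
        for c in range(snap.n_cells):
            rows.append(
                (
                    snap.t,
                    level,
                    c,
                    snap.pos[c, 0],
                    snap.pos[c, 1],
                    *snap.a_y[c],
                    *snap.mu[c],
                    *sigma[c],
                    fe[c],
                )
            )
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)


def trajectory_frame(
    traj: Trajectory | HierarchyTrajectory,
) -> pd.DataFrame:
    """Long-format table for a level-1 or hierarchical trajectory."""
    if isinstance(traj, HierarchyTrajectory):
        return pd.concat(
            [_frame_for(traj.local, "local"), _frame_for(traj.macro, "global")],
            ignore_index=True,
        )
    return _frame_for(traj, "local")


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Write a level-1 trajectory as long-format CSV (exact round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trajectory_frame(traj).to_csv(path, index=False, float_format="%.17g")
    return path


def write_hierarchy_trajectory(traj: HierarchyTrajectory, path: str | Path) -> Path:
    """Write both levels of a hierarchical trajectory into one CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trajectory_frame(traj).to_csv(path, index=False, float_format="%.17g")
    return path


def read_trajectory(path: str | Path) -> pd.DataFrame:
    """Read a trajectory CSV back into a table (numbers exact)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"trajectory file lacks columns: {missing}")
    return df


def state_from_frame(
    df: pd.DataFrame, cfg: SimConfig, level: str = "local"
) -> EnsembleState:
    """Rebuild the final snapshot of one level from a trajectory table."""
    sub = df[df["level"] == level]
    if sub.empty:
        raise InvalidInputError(f"no rows for level {level!r}")
    t_final = sub["time"].max()
    final = sub[sub["time"] == t_final].sort_values("cell")
    pos = final[["x", "y"]].to_numpy(dtype=float)
    a_y = final[["secretion_1", "secretion_2", "secretion_3"]].to_numpy(dtype=float)
    mu = final[["belief_1", "belief_2", "belief_3"]].to_numpy(dtype=float)
    s_alpha = all_extracellular(pos, a_y, cfg.kernel)
    return _bookkeep(pos, a_y, mu, a_y.copy(), s_alpha, cfg, t=float(t_final))


def _ring_positions(n: int, radius: float, phase: float = 0.0) -> np.ndarray:
    th = 2.0 * np.pi * np.arange(n) / n + phase
    return radius * np.stack([np.cos(th), np.sin(th)], axis=1)


def make_fixture(
    kind: str, seed: int = 0, cfg: Optional[SimConfig] = None
) -> EnsembleState:
    """Construct reference configurations for metric validation.

    ``converged_level1``: one internal cell at the origin, five active cells
    equally spaced on the unit circle, ten sensory cells on the circle of
    radius 2, with near-one-hot beliefs — the idealised converged blanket.
    ``shuffled``: the same positions with the type labels permuted by
    ``seed`` (a geometry that should *fail* the blanket metrics).
    ``converged_hierarchy``: sixteen macro-agents in the same pattern at the
    global scale (radii multiplied by 4).
    """
    if kind not in FIXTURE_KINDS:
        raise InvalidInputError(f"unknown fixture kind: {kind!r}")
    if cfg is None:
        cfg = SimConfig()
    scale = 4.0 if kind == "converged_hierarchy" else 1.0
    pos = np.vstack(
        [
            np.zeros((1, 2)),
            _ring_positions(5, 1.0 * scale),
            _ring_positions(10, 2.0 * scale, phase=0.1),
        ]
    )
    labels = np.array(
        [TypeIndex.INTERNAL.index] * 1
        + [TypeIndex.ACTIVE.index] * 5
        + [TypeIndex.SENSORY.index] * 10
    )
    if kind == "shuffled":
        rng = np.random.default_rng(seed)
        labels = rng.permutation(labels)
    mu = 20.0 * np.eye(N_TYPES)[labels]
    a_y = model_core.predict(mu, cfg.priors).s_y
    kernel = cfg.kernel
    if kind == "converged_hierarchy":
        kernel = type(cfg.kernel)(
            form=cfg.kernel.form, length_scale=cfg.kernel.length_scale * 4.0
        )
        cfg = replace(cfg, kernel=kernel)
    s_alpha = all_extracellular(pos, a_y, kernel)
    return _bookkeep(pos, a_y, mu, a_y.copy(), s_alpha, cfg, t=0.0)
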