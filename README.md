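# blanketsim

Active-inference simulation of Markov blanket self-organisation.

Sixteen initially identical ("pluripotent") cells each hold a belief about
which of three roles they play — **sensory**, **active** or **internal** —
and minimise a shared variational free energy by updating beliefs, secreting
chemical signals and moving through a 2-D signalling field.  With no target
morphology and no prescribed type counts, the ensemble differentiates and
arranges itself into a Markov blanket: an internal core, an active ring and
a sensory periphery.  A second, hierarchical mode couples sixteen such
ensembles through a mean-field approximation, so the same self-organisation
recurs one level up ("blankets of blankets").

## Quick start

```bash
# single-level run with the reference defaults
blanketsim run-ensemble --seed 0 --out runs/level1

# two-level (hierarchical) run
blanketsim run-hierarchy --seed 0 --out runs/hier

# re-analyse a saved trajectory
blanketsim analyze --traj runs/level1/trajectory.csv --out runs/level1-analysis

# render snapshot frames (optionally an animated GIF)
blanketsim render --traj runs/level1/trajectory.csv --out runs/frames --animate

# construct reference fixtures for the metrics
blanketsim fixtures --kind converged_level1 --out runs/fixture
```

Every run directory receives `config.json` (the fully resolved
configuration), `trajectory.csv` (long format: one row per cell per snapshot
per level), `report.json` (blanket diagnostics) and `run.log`.

Python API:

```python
from blanketsim.ensemble_sim import SimConfig, run
from blanketsim.blanket_metrics import report

traj = run(SimConfig(seed=0))
print(report(traj.snapshots[-1], traj.config).to_dict())
```

## Configuration

Runs are configured by a YAML file with sections `model`, `world`,
`integration`, `hierarchy`, `metrics` and `output`; every key has a default
equal to the reference configuration, so an empty file (or no file) is
valid.  Unknown keys are an error.  Example:

```yaml
integration:
  n_steps: 32768
  seed: 3
world:
  n_cells: 16
hierarchy:
  n_ensembles: 16
  global_gain: 0.25
```

## Conventions

- Every length-3 vector is ordered `(sensory, active, internal)`.
- Rendered colours: sensory = blue, active = green, internal = red; a
  pluripotent cell is an equal grey mixture.
- A cell is *committed* when its largest type expectation (softmax of the
  belief) exceeds the commit threshold (default 0.9).

## Diagnostics

`blanketsim.blanket_metrics.report` checks that a configuration really is a
blanket: all cells committed, all three types present, radial ordering
internal < active < sensory around the committed centroid, and an
independence ratio (direct internal–sensory kernel coupling relative to the
blanket-mediated internal–active coupling) below 0.5.  `commit_times` and
`free_energy_descent` quantify convergence.  See `docs/methods.md` for the
model equations, the calibration method for the default prior matrices, and
known limitations.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` runs the full reference configurations and takes
a few minutes; the remaining modules are fast unit and oracle tests.
`scripts/acceptance.py --seed N --out results.json` runs the default
hierarchical simulation and reports the number of macro-agents committing to
a global type.
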