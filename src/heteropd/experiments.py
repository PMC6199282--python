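"""Parameter sweeps: cooperation curves, phase planes, snapshot series.

These reproduce the standard observables of the model: the equilibrium
cooperator fraction rho_c as a function of the temptation b, the
preference parameter alpha, or the environment weight u, plus
two-dimensional phase planes (b-u, b-alpha, alpha-u) and strategy
snapshots along a single run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .model_core import ConfigurationError, SimulationParams
from .protocol import EnsembleResult, run_ensemble, run_single

__all__ = [
    "SWEEPABLE",
    "SweepSpec",
    "SweepResult",
    "default_grid",
    "point_seed",
    "sweep",
    "locate_optimum",
    "snapshot_series",
    "same_strategy_pair_fraction",
]

#: Parameters that may serve as sweep axes.
SWEEPABLE = ("b", "u", "alpha", "K", "L")

#: Conventional axis grids for the model's standard observables.
_DEFAULT_GRIDS = {
    "b": np.round(np.arange(1.0, 1.5001, 0.05), 10),
    "u": np.round(np.arange(0.0, 1.0001, 0.1), 10),
    "alpha": np.arange(0.0, 12.001, 1.0),
}


def default_grid(name: str) -> np.ndarray:
    """Default axis grid for b, u or alpha."""
    try:
        return _DEFAULT_GRIDS[name].copy()
    except KeyError:
        raise ConfigurationError(f"no default grid for parameter {name!r}") from None


def _check_axis(axis: tuple[str, list]) -> tuple[str, list]:
    name, values = axis
    if name not in SWEEPABLE:
        raise ConfigurationError(
            f"axis parameter must be one of {SWEEPABLE}, got {name!r}"
        )
    values = list(values)
    if not values:
        raise ConfigurationError(f"axis {name!r} has no values")
    if any(b <= a for a, b in zip(values, values[1:])):
        raise ConfigurationError(f"axis {name!r} values must be strictly increasing")
    return name, values


@dataclass
class SweepSpec:
    """A 1D or 2D grid of ensemble runs over sweepable parameters."""

    base_params: SimulationParams
    axis1: tuple[str, list]
    axis2: Optional[tuple[str, list]] = None
    output_path: Optional[str] = None

    def __post_init__(self) -> None:
        self.axis1 = _check_axis(self.axis1)
        if self.axis2 is not None:
            self.axis2 = _check_axis(self.axis2)
            if self.axis2[0] == self.axis1[0]:
                raise ConfigurationError("the two sweep axes must differ")


@dataclass
class SweepResult:
    """Grid of ensemble results (None where a point failed)."""

    spec: SweepSpec
    grid: list  # axis1-major nested list of EnsembleResult | None
    errors: dict[tuple, str] = field(default_factory=dict)
    master_seed: int = 0

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: axis value(s), rho_mean, rho_sd, n_replicates."""
        name1, vals1 = self.spec.axis1
        rows = []
        if self.spec.axis2 is None:
            for v1, res in zip(vals1, self.grid):
                rows.append(_row({name1: v1}, res))
        else:
            name2, vals2 = self.spec.axis2
            for v1, line in zip(vals1, self.grid):
                for v2, res in zip(vals2, line):
                    rows.append(_row({name1: v1, name2: v2}, res))
        return pd.DataFrame(rows)


def _row(axes: dict, res: Optional[EnsembleResult]) -> dict:
    out = dict(axes)
    if res is None:
        out.update(rho_mean=np.nan, rho_sd=np.nan, n_replicates=0)
    else:
        out.update(
            rho_mean=res.rho_mean, rho_sd=res.rho_sd, n_replicates=res.n_replicates
        )
    return out


def point_seed(master_seed: int, values: tuple) -> int:
    """Deterministic per-grid-point seed from the master seed and axis values.

    Hashing the values (not the grid index) means adding points to a grid
    never changes the seeds of existing points.
    """
    enc = [int(master_seed)] + [int(round(float(v) * 1_000_000)) for v in values]
    return int(np.random.SeedSequence(enc).generate_state(1)[0])


def _point_params(base: SimulationParams, updates: dict) -> SimulationParams:
    cast = {k: (int(v) if k == "L" else float(v)) for k, v in updates.items()}
    return base.with_(**cast)


def sweep(spec: SweepSpec) -> SweepResult:
    """Run an ensemble at every grid point with deterministic per-point seeds.

    A failure at one point marks that point invalid and the sweep
    continues; failed points are listed in ``SweepResult.errors``.
    """
    master = spec.base_params.seed
    name1, vals1 = spec.axis1
    grid: list = []
    errors: dict[tuple, str] = {}

    def run_point(updates: dict, key: tuple):
        try:
            p = _point_params(spec.base_params, updates)
            p = p.with_(seed=point_seed(master, key))
            return run_ensemble(p)
        except Exception as exc:  # point-level isolation, sweep continues
            errors[key] = f"{type(exc).__name__}: {exc}"
            return None

    if spec.axis2 is None:
        for v1 in vals1:
            grid.append(run_point({name1: v1}, (v1,)))
    else:
        name2, vals2 = spec.axis2
        for v1 in vals1:
            line = [run_point({name1: v1, name2: v2}, (v1, v2)) for v2 in vals2]
            grid.append(line)
    return SweepResult(spec=spec, grid=grid, errors=errors, master_seed=master)


def locate_optimum(result: SweepResult, axis: str) -> tuple[float, float]:
    """Grid value maximizing the mean cooperator fraction along a 1D sweep.

    Ties break toward the smaller parameter value.  Invalid points are
    excluded; if every point failed, an error is raised.
    """
    name, vals = result.spec.axis1
    if result.spec.axis2 is not None:
        raise ConfigurationError("locate_optimum requires a 1D sweep")
    if axis != name:
        raise ConfigurationError(f"sweep axis is {name!r}, not {axis!r}")
    best: Optional[tuple[float, float]] = None
    for v, res in zip(vals, result.grid):
        if res is None:
            continue
        if best is None or res.rho_mean > best[1]:
            best = (v, res.rho_mean)
    if best is None:
        raise ConfigurationError("every sweep point is invalid")
    return best


def snapshot_series(
    params: SimulationParams, seed: int
) -> list[tuple[int, np.ndarray]]:
    """Strategy grids of a single run at the requested MCS indices, in order."""
    if not params.snapshot_times:
        raise ConfigurationError("snapshot_times is empty")
    res = run_single(params, seed)
    return [(t, res.snapshots[t]) for t in sorted(set(params.snapshot_times))]


def same_strategy_pair_fraction(strategies: np.ndarray) -> float:
    """Fraction of nearest-neighbour pairs with equal strategies.

    A simple clustering statistic: 0.5 for a random half-half grid, 1 for
    a uniform grid.  Each torus pair is counted once (right and down
    bonds).
    """
    s = np.asarray(strategies)
    same_right = s == np.roll(s, -1, axis=1)
    same_down = s == np.roll(s, -1, axis=0)
    return float((same_right.sum() + same_down.sum()) / (2 * s.size))
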