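"""Measurement protocol: run scheduling, stationarity, equilibrium, ensembles.

A run executes ``total_mcs`` full sweeps, records the cooperator fraction
after every sweep, and estimates the equilibrium value as the mean over
the final ``avg_window`` sweeps.  The stationarity criterion compares the
means of the last two non-overlapping windows; if they differ by at least
the tolerance, the run is extended block by block (up to a hard cap)
before averaging.  Once the lattice reaches an absorbing state (all
cooperators or all defectors) the remaining trajectory is filled with the
constant value without further sweeps.

Ensembles average the equilibrium over independent replicates, each with
a freshly drawn lattice and heterogeneity field.  All randomness derives
from the master seed through a counter-based scheme (seed, replicate
index), so ensembles are reproducible and replicates could be executed in
any order or in parallel without changing the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _kernel
from .dynamics import selection_cdf_table
from .model_core import (
    LatticeState,
    PayoffMatrix,
    RunResult,
    SimulationParams,
    init_lattice,
)

__all__ = [
    "ReplicateSummary",
    "EnsembleResult",
    "stationarity_check",
    "child_seed",
    "run_single",
    "run_ensemble",
    "desk_scale_params",
]


def desk_scale_params(**overrides) -> SimulationParams:
    """Desk-scale protocol: L=50, 7000 MCS averaging the last 2000.

    A scaled-down counterpart of the full protocol (L=100, 6x10^4 MCS
    averaging the last 10^4) for interactive work and tests.  The
    fluctuation threshold of the stationarity check was calibrated for
    10^4-sweep windows on 10^4 sites and sits at the margin for the
    shorter, noisier desk-scale windows, so extensions are capped at 2
    here; equilibrium estimates are unaffected beyond sampling noise.
    """
    base = dict(L=50, total_mcs=7000, avg_window=2000, max_extensions=2, n_replicates=5)
    base.update(overrides)
    return SimulationParams(**base)


@dataclass(frozen=True)
class ReplicateSummary:
    """Slim per-replicate record kept inside an ensemble."""

    seed: int
    rho_equilibrium: float
    mcs_executed: int
    stationary: bool


@dataclass
class EnsembleResult:
    """Replicate-averaged equilibrium cooperator fraction with dispersion."""

    params: SimulationParams
    rho_mean: float
    rho_sd: float
    per_replicate: list[ReplicateSummary]
    seeds: list[int] = field(default_factory=list)

    @property
    def n_replicates(self) -> int:
        return len(self.per_replicate)

    @property
    def rho_se(self) -> float:
        """Standard error of the replicate mean (0 for a single replicate)."""
        n = self.n_replicates
        return self.rho_sd / np.sqrt(n) if n > 1 else 0.0


def stationarity_check(trajectory: np.ndarray, window: int, tol: float) -> bool:
    """True iff the last two non-overlapping window means differ by less than tol.

    The comparison is strict, so a difference exactly at the tolerance
    fails the check.
    """
    traj = np.asarray(trajectory, dtype=np.float64)
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window!r}")
    if traj.size < 2 * window:
        raise ValueError(
            f"trajectory of length {traj.size} is too short for two windows of {window}"
        )
    last = traj[-window:].mean()
    prev = traj[-2 * window : -window].mean()
    return bool(abs(last - prev) < tol)


def child_seed(master_seed: int, index: int) -> int:
    """Deterministic per-replicate seed derived from (master seed, counter)."""
    return int(np.random.SeedSequence((master_seed, index)).generate_state(1)[0])


def _run_block(
    state: LatticeState,
    params: SimulationParams,
    rng: np.random.Generator,
    sel_cdf: np.ndarray,
    M: np.ndarray,
    traj: np.ndarray,
    start_mcs: int,
    n_sweeps: int,
    snapshot_set: set[int],
    snapshots: dict[int, np.ndarray],
) -> int:
    """Advance ``n_sweeps`` MCS, filling traj[start+1 .. start+n]; returns ncoop.

    Short-circuits once an absorbing state is reached: the rest of the
    block is filled with the constant fraction and the frozen grid serves
    for any remaining snapshot times.
    """
    n = params.n_sites
    strat = state.strategies.reshape(-1)
    env = state.env_field.reshape(-1)
    nbr = state.neighbor_table
    ncoop = state.n_cooperators()
    mcs = start_mcs
    end = start_mcs + n_sweeps
    while mcs < end:
        if ncoop == 0 or ncoop == n:
            rho = ncoop / n
            traj[mcs + 1 : end + 1] = rho
            for t in snapshot_set:
                if mcs < t <= end:
                    snapshots[t] = state.strategies.copy()
            return ncoop
        rand = rng.random((n, 3))
        ncoop = _kernel.sweep(strat, nbr, sel_cdf, env, M, params.u, params.K, rand, ncoop)
        mcs += 1
        traj[mcs] = ncoop / n
        if mcs in snapshot_set:
            snapshots[mcs] = state.strategies.copy()
    return ncoop


def run_single(
    params: SimulationParams,
    seed: int,
    h_field: Optional[np.ndarray] = None,
    keep_h_field: bool = False,
) -> RunResult:
    """Execute one seeded run of the full measurement protocol.

    Initializes a lattice, runs ``total_mcs`` sweeps recording the
    cooperator fraction after each, records snapshots at the requested
    MCS indices (0 = initial condition), then applies the stationarity
    check and extends by ``extension_block`` sweeps at a time until it
    passes or ``max_extensions`` is exhausted (the result is then flagged
    non-stationary).  The equilibrium estimate is the mean over the final
    ``avg_window`` entries of the (possibly extended) trajectory.
    """
    rng = np.random.default_rng(seed)
    state = init_lattice(params, rng, h_field)
    sel_cdf = selection_cdf_table(state.h_field, params.alpha)
    M = PayoffMatrix.weak_pd(params.b).as_array()
    n = params.n_sites

    snapshot_set = set(params.snapshot_times)
    snapshots: dict[int, np.ndarray] = {}
    if 0 in snapshot_set:
        snapshots[0] = state.strategies.copy()

    traj = np.empty(params.total_mcs + 1, dtype=np.float64)
    traj[0] = state.rho_c()
    ncoop = _run_block(
        state, params, rng, sel_cdf, M, traj, 0, params.total_mcs, snapshot_set, snapshots
    )

    window = params.avg_window
    block = params.effective_extension_block
    extensions = 0
    stationary = True
    while True:
        absorbed = ncoop == 0 or ncoop == n
        if absorbed:
            break
        if traj.size - 1 < 2 * window:
            # too short to compare two windows; accept the scheduled run
            break
        if stationarity_check(traj[1:], window, params.stationarity_tol):
            break
        if extensions >= params.max_extensions:
            stationary = False
            break
        start = traj.size - 1
        traj = np.concatenate([traj, np.empty(block)])
        ncoop = _run_block(
            state, params, rng, sel_cdf, M, traj, start, block, snapshot_set, snapshots
        )
        extensions += 1

    mcs_executed = traj.size - 1
    rho_eq = float(traj[-window:].mean())
    return RunResult(
        rho_trajectory=traj,
        rho_equilibrium=rho_eq,
        mcs_executed=mcs_executed,
        stationary=stationary,
        snapshots=snapshots,
        seed=int(seed),
        h_field=state.h_field if keep_h_field else None,
    )


def run_ensemble(
    params: SimulationParams,
    seeds: Optional[Sequence[int]] = None,
    shared_h_field: bool = False,
) -> EnsembleResult:
    """Average ``n_replicates`` independent runs of :func:`run_single`.

    Child seeds derive deterministically from ``params.seed`` unless an
    explicit ``seeds`` sequence is given.  Each replicate redraws its own
    heterogeneity field; ``shared_h_field=True`` instead draws one field
    from the master seed and reuses it across all replicates.
    """
    if seeds is None:
        seeds = [child_seed(params.seed, r) for r in range(params.n_replicates)]
    else:
        seeds = [int(s) for s in seeds]
        if len(seeds) != params.n_replicates:
            raise ValueError(
                f"expected {params.n_replicates} seeds, got {len(seeds)}"
            )

    h_field = None
    if shared_h_field:
        from .model_core import H_LEVELS

        # distinct stream from any replicate counter
        h_rng = np.random.default_rng(np.random.SeedSequence((params.seed, 0x68F1E1D)))
        h_field = H_LEVELS[h_rng.integers(0, len(H_LEVELS), size=(params.L, params.L))]

    summaries = []
    for s in seeds:
        res = run_single(params, s, h_field=h_field)
        summaries.append(
            ReplicateSummary(
                seed=s,
                rho_equilibrium=res.rho_equilibrium,
                mcs_executed=res.mcs_executed,
                stationary=res.stationary,
            )
        )
    eq = np.array([r.rho_equilibrium for r in summaries])
    return EnsembleResult(
        params=params,
        rho_mean=float(eq.mean()),
        rho_sd=float(eq.std(ddof=1)) if len(eq) > 1 else 0.0,
        per_replicate=summaries,
        seeds=list(seeds),
    )
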