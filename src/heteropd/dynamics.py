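"""Stochastic update kernel: preference selection, Fermi imitation, MC sweeps.

One elementary update: pick a focal player x uniformly at random, compute
its fitness F_x = (1-u) P_x + u H_x from its instantaneous payoff and its
quenched environment, draw a model neighbour y with probability
Omega_y proportional to exp(alpha * h_y), compute F_y the same way, and
let x adopt s_y with the Fermi probability

    W(y -> x) = 1 / (1 + exp((F_x - F_y) / K)).

One full Monte Carlo step (MCS) is L^2 such updates with independent
uniform focal draws (random sequential order), so every player is
updated once on average.

Random numbers are consumed in a fixed order inside each elementary
update (focal draw, neighbour draw, adoption draw); the adoption draw is
performed even when x and y already agree.  This makes seeded runs
bit-reproducible and lets the compiled sweep in :mod:`heteropd._kernel`
replay exactly the same stream as the pure-Python step here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernel
from .model_core import (
    LatticeState,
    PayoffMatrix,
    SimulationParams,
    game_payoff,
    neighbor_sites,
)

__all__ = [
    "UpdateEvent",
    "selection_probabilities",
    "selection_cdf_table",
    "fermi_probability",
    "elementary_step",
    "mcs_sweep",
]


@dataclass(frozen=True)
class UpdateEvent:
    """Diagnostic record of one elementary update."""

    focal: tuple[int, int]
    chosen_neighbor: tuple[int, int]
    focal_fitness: float
    neighbor_fitness: float
    adopted: bool


def selection_probabilities(
    h_field: np.ndarray, site: tuple[int, int], alpha: float
) -> np.ndarray:
    """Softmax over the four neighbours' h values, Omega_y ∝ exp(alpha * h_y).

    The exponents are shifted by their maximum before exponentiating, so
    arbitrarily large alpha cannot overflow.  alpha = 0 reduces to the
    uniform choice of the standard model.  Order: up, down, left, right.
    """
    if alpha < 0.0:
        raise ValueError(f"alpha must be >= 0, got {alpha!r}")
    L = h_field.shape[0]
    r, c = site
    h = np.array([h_field[rr, cc] for rr, cc in neighbor_sites(L, r, c)])
    z = alpha * h
    w = np.exp(z - z.max())
    return w / w.sum()


def selection_cdf_table(h_field: np.ndarray, alpha: float) -> np.ndarray:
    """Per-site cumulative neighbour-selection probabilities, shape (L*L, 4).

    The table is quenched (it depends only on h and alpha), so it is
    computed once per run and shared by the Python and compiled paths.
    """
    L = h_field.shape[0]
    cdf = np.empty((L * L, 4), dtype=np.float64)
    for r in range(L):
        for c in range(L):
            cdf[r * L + c] = np.cumsum(selection_probabilities(h_field, (r, c), alpha))
    return cdf


def fermi_probability(f_focal: float, f_neighbor: float, K: float) -> float:
    """Probability that the focal player adopts the neighbour's strategy."""
    if K <= 0.0:
        raise ValueError(f"K must be > 0, got {K!r}")
    try:
        return 1.0 / (1.0 + math.exp((f_focal - f_neighbor) / K))
    except OverflowError:
        # exp overflow means an overwhelming fitness advantage of the focal
        return 0.0


def _uniform_to_site(u0: float, n_sites: int) -> int:
    site = int(u0 * n_sites)
    return n_sites - 1 if site == n_sites else site


def elementary_step(
    state: LatticeState,
    params: SimulationParams,
    rng: np.random.Generator,
    *,
    focal: tuple[int, int] | None = None,
    sel_cdf: np.ndarray | None = None,
) -> UpdateEvent:
    """One elementary update, mutating ``state`` in place.

    ``focal`` overrides the uniform focal draw (used by the oracle tests);
    the focal uniform is still consumed so the stream layout is unchanged.
    ``sel_cdf`` may pass a precomputed :func:`selection_cdf_table`.
    """
    L = state.L
    u0, u1, u2 = rng.random(3)
    if focal is None:
        flat = _uniform_to_site(u0, L * L)
        focal = (flat // L, flat % L)
    payoffs = PayoffMatrix.weak_pd(params.b)

    f_x = (1.0 - params.u) * game_payoff(state, focal, payoffs) + params.u * state.env_field[
        focal
    ]

    if sel_cdf is not None:
        cdf = sel_cdf[focal[0] * L + focal[1]]
    else:
        cdf = np.cumsum(selection_probabilities(state.h_field, focal, params.alpha))
    j = int(np.searchsorted(cdf, u1, side="right"))
    j = min(j, 3)
    neighbor = neighbor_sites(L, *focal)[j]

    f_y = (1.0 - params.u) * game_payoff(state, neighbor, payoffs) + params.u * state.env_field[
        neighbor
    ]

    w = fermi_probability(f_x, f_y, params.K)
    adopted = bool(u2 < w)
    if adopted:
        state.strategies[focal] = state.strategies[neighbor]
    return UpdateEvent(
        focal=focal,
        chosen_neighbor=neighbor,
        focal_fitness=f_x,
        neighbor_fitness=f_y,
        adopted=adopted,
    )


def mcs_sweep(
    state: LatticeState,
    params: SimulationParams,
    rng: np.random.Generator,
    *,
    sel_cdf: np.ndarray | None = None,
    compiled: bool = True,
) -> float:
    """One full MCS (L^2 elementary updates); returns the new cooperator fraction.

    ``compiled=True`` runs the numba kernel; ``compiled=False`` loops the
    pure-Python :func:`elementary_step`.  Both consume the same uniforms
    and yield bit-identical states.
    """
    n = state.L * state.L
    if sel_cdf is None:
        sel_cdf = selection_cdf_table(state.h_field, params.alpha)
    if compiled:
        rand = rng.random((n, 3))
        ncoop = _kernel.sweep(
            state.strategies.reshape(-1),
            state.neighbor_table,
            sel_cdf,
            state.env_field.reshape(-1),
            PayoffMatrix.weak_pd(params.b).as_array(),
            params.u,
            params.K,
            rand,
            state.n_cooperators(),
        )
        return ncoop / n
    for _ in range(n):
        elementary_step(state, params, rng, sel_cdf=sel_cdf)
    return state.rho_c()
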