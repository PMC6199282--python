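"""Independent exact calculators for testing the stochastic kernel.

Everything here is straight-line arithmetic written separately from the
dynamics code (no shared helpers), so agreement between a Monte Carlo
frequency and these closed forms is evidence, not tautology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model_core import LatticeState, SimulationParams, neighbor_sites

__all__ = [
    "LocalConfiguration",
    "exact_flip_probability",
    "exact_one_step_distribution",
]


@dataclass(frozen=True)
class LocalConfiguration:
    """Everything entering one elementary update around a focal site.

    ``nbr_strategies[i]`` / ``nbr_h[i]`` describe neighbour i of the focal
    player; ``nbr_nbr_strategies[i]`` / ``nbr_nbr_h[i]`` list the four
    neighbours of neighbour i (needed for its payoff and environment).
    Strategies are coded D=0, C=1.
    """

    focal_strategy: int
    focal_h: float
    nbr_strategies: tuple[int, int, int, int]
    nbr_h: tuple[float, float, float, float]
    nbr_nbr_strategies: tuple[Sequence[int], ...]
    nbr_nbr_h: tuple[Sequence[float], ...]
    b: float
    u: float
    alpha: float
    K: float

    def __post_init__(self) -> None:
        if len(self.nbr_strategies) != 4 or len(self.nbr_h) != 4:
            raise ValueError("a focal site has exactly 4 neighbours")
        if len(self.nbr_nbr_strategies) != 4 or len(self.nbr_nbr_h) != 4:
            raise ValueError("each neighbour needs its own 4-neighbourhood")
        for i in range(4):
            if len(self.nbr_nbr_strategies[i]) != 4 or len(self.nbr_nbr_h[i]) != 4:
                raise ValueError(f"neighbour {i} is missing part of its neighbourhood")

    @classmethod
    def from_lattice(
        cls, state: LatticeState, site: tuple[int, int], params: SimulationParams
    ) -> "LocalConfiguration":
        L = state.L
        nbrs = neighbor_sites(L, *site)
        return cls(
            focal_strategy=int(state.strategies[site]),
            focal_h=float(state.h_field[site]),
            nbr_strategies=tuple(int(state.strategies[p]) for p in nbrs),
            nbr_h=tuple(float(state.h_field[p]) for p in nbrs),
            nbr_nbr_strategies=tuple(
                tuple(int(state.strategies[q]) for q in neighbor_sites(L, *p)) for p in nbrs
            ),
            nbr_nbr_h=tuple(
                tuple(float(state.h_field[q]) for q in neighbor_sites(L, *p)) for p in nbrs
            ),
            b=params.b,
            u=params.u,
            alpha=params.alpha,
            K=params.K,
        )


def _pd_payoff(s_row: int, s_col: int, b: float) -> float:
    # weak PD: (C,C)=1, (C,D)=0, (D,C)=b, (D,D)=0
    if s_row == 1:
        return 1.0 if s_col == 1 else 0.0
    return b if s_col == 1 else 0.0


def exact_flip_probability(config: LocalConfiguration) -> float:
    """Probability that one forced update of the focal player changes its strategy.

    Sums, over the neighbours carrying the opposite strategy, the product
    of the preference-selection probability and the Fermi adoption
    probability, all evaluated in closed form.
    """
    c = config
    # selection weights over the neighbours
    weights = [math.exp(c.alpha * h) for h in c.nbr_h]
    wsum = sum(weights)

    # focal fitness
    p_x = sum(_pd_payoff(c.focal_strategy, s, c.b) for s in c.nbr_strategies)
    h_env_x = sum(c.nbr_h) / 4.0
    f_x = (1.0 - c.u) * p_x + c.u * h_env_x

    prob = 0.0
    for i in range(4):
        if c.nbr_strategies[i] == c.focal_strategy:
            continue
        p_y = sum(
            _pd_payoff(c.nbr_strategies[i], s, c.b) for s in c.nbr_nbr_strategies[i]
        )
        h_env_y = sum(c.nbr_nbr_h[i]) / 4.0
        f_y = (1.0 - c.u) * p_y + c.u * h_env_y
        w_fermi = 1.0 / (1.0 + math.exp((f_x - f_y) / c.K))
        prob += (weights[i] / wsum) * w_fermi
    return prob


def exact_one_step_distribution(
    state: LatticeState, params: SimulationParams
) -> tuple[np.ndarray, float]:
    """Per-site flip probabilities of one elementary update from a frozen state.

    Entry (r, c) is the probability that the update flips that site,
    including the uniform 1/L^2 focal draw; the returned scalar is the
    complementary no-flip mass, so everything sums to one.  Intended for
    small lattices (exhaustive enumeration over sites).
    """
    L = state.L
    n = L * L
    flips = np.zeros((L, L), dtype=np.float64)
    for r in range(L):
        for c in range(L):
            cfg = LocalConfiguration.from_lattice(state, (r, c), params)
            flips[r, c] = exact_flip_probability(cfg) / n
    return flips, float(1.0 - flips.sum())
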