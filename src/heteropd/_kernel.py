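"""Compiled inner loop for full Monte Carlo sweeps.

The kernel consumes pre-drawn uniforms (three per elementary update, in
the fixed order focal / neighbour / adoption) so that the pure-Python
reference step in :mod:`heteropd.dynamics` and this compiled path walk
the identical random stream and produce bit-identical trajectories.
"""

from __future__ import annotations

import math

import numba
import numpy as np


@numba.njit(cache=True)
def sweep(
    strat: np.ndarray,       # flat int8 strategies, D=0 / C=1 (mutated in place)
    nbr: np.ndarray,         # (N, 4) neighbour indices, order up/down/left/right
    sel_cdf: np.ndarray,     # (N, 4) cumulative neighbour-selection probabilities
    env: np.ndarray,         # flat quenched environment field H
    M: np.ndarray,           # 2x2 payoff lookup M[s_row, s_col]
    u: float,
    K: float,
    rand: np.ndarray,        # (n_steps, 3) uniforms: focal, neighbour, adoption
    ncoop: int,
) -> int:
    """Run ``rand.shape[0]`` elementary updates; return the cooperator count."""
    N = strat.shape[0]
    one_minus_u = 1.0 - u
    for t in range(rand.shape[0]):
        x = int(rand[t, 0] * N)
        if x == N:                     # guard against rand exactly 1.0
            x = N - 1
        sx = strat[x]
        # focal payoff, fixed neighbour order
        px = 0.0
        for j in range(4):
            px += M[sx, strat[nbr[x, j]]]
        fx = one_minus_u * px + u * env[x]
        # preference selection among the 4 neighbours
        u1 = rand[t, 1]
        j = 0
        while j < 3 and u1 >= sel_cdf[x, j]:
            j += 1
        y = nbr[x, j]
        sy = strat[y]
        py = 0.0
        for j2 in range(4):
            py += M[sy, strat[nbr[y, j2]]]
        fy = one_minus_u * py + u * env[y]
        # Fermi adoption; the draw happens even when sx == sy so the
        # random stream does not depend on the configuration
        w = 1.0 / (1.0 + math.exp((fx - fy) / K))
        if rand[t, 2] < w and sy != sx:
            ncoop += sy - sx
            strat[x] = sy
    return ncoop
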