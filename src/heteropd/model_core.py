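"""Static parts of the lattice model: parameters, payoffs, heterogeneity, fitness.

The population lives on an L x L square lattice with periodic boundaries.
Each site x holds a strategy s_x in {C, D}, a quenched heterogeneity value
h_x drawn from the 41-level grid {0.0, 0.1, ..., 4.0}, and an environment
value H_x equal to the arithmetic mean of the h values of its four von
Neumann neighbours (the site's own h is excluded).  Fitness mixes game
payoff and environment linearly:

    F_x = (1 - u) * P_x + u * H_x,   u in [0, 1].

The game is the weak prisoner's dilemma: T = b > 1, R = 1, P = S = 0, so
the temptation b is the single dilemma-strength parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "ConfigurationError",
    "SimulationParams",
    "PayoffMatrix",
    "LatticeState",
    "RunResult",
    "H_LEVELS",
    "neighbor_indices",
    "neighbor_sites",
    "init_lattice",
    "game_payoff",
    "environment",
    "environment_field",
    "fitness",
]

#: The 41 equiprobable heterogeneity levels {0.0, 0.1, ..., 4.0}.
H_LEVELS = np.arange(41) * 0.1


class ConfigurationError(ValueError):
    """Raised when a simulation parameter is missing, unknown or out of range."""


@dataclass(frozen=True)
class SimulationParams:
    """Complete, immutable description of one experiment.

    Parameters
    ----------
    L
        Lattice side length; the population has ``L * L`` sites.
    b
        Temptation to defect ``T = b`` (>= 1); the only nonzero off-diagonal
        payoff of the weak prisoner's dilemma.
    u
        Weight of the environment in fitness, in ``[0, 1]``.  ``u = 0`` is
        the traditional game (fitness = payoff); ``u = 1`` makes fitness
        entirely environmental, decoupling the dynamics from the game.
    alpha
        Preference-selection parameter (>= 0).  The neighbour to imitate is
        drawn with probability proportional to ``exp(alpha * h_y)``;
        ``alpha = 0`` is uniform random choice.
    K
        Noise amplitude of the Fermi imitation rule (> 0).
    total_mcs
        Scheduled full Monte Carlo steps (one MCS = ``L**2`` elementary
        updates).
    avg_window
        Number of final MCS averaged to estimate the equilibrium
        cooperator fraction; also the window of the stationarity check.
    stationarity_tol
        Threshold on the difference of consecutive window means below
        which the run is declared stationary.
    extension_block
        MCS appended when the stationarity check fails (``None`` defaults
        to ``avg_window``).
    max_extensions
        Hard cap on the number of extensions before the run is flagged
        non-stationary.
    n_replicates
        Independent runs per ensemble, each with its own lattice and its
        own heterogeneity field.
    seed
        Master seed from which all per-replicate streams derive.
    snapshot_times
        MCS indices at which the strategy grid is recorded (0 = initial
        condition).
    """

    L: int = 100
    b: float = 1.1
    u: float = 0.0
    alpha: float = 0.0
    K: float = 0.1
    total_mcs: int = 60_000
    avg_window: int = 10_000
    stationarity_tol: float = 1e-2
    extension_block: Optional[int] = None
    max_extensions: int = 10
    n_replicates: int = 40
    seed: int = 0
    snapshot_times: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "snapshot_times", tuple(int(t) for t in self.snapshot_times))
        if not (isinstance(self.L, (int, np.integer)) and self.L >= 2):
            raise ConfigurationError(f"L must be an integer >= 2, got {self.L!r}")
        if not self.b >= 1.0:
            raise ConfigurationError(f"b must be >= 1 (weak PD temptation), got {self.b!r}")
        if not 0.0 <= self.u <= 1.0:
            raise ConfigurationError(f"u must lie in [0, 1], got {self.u!r}")
        if not self.alpha >= 0.0:
            raise ConfigurationError(f"alpha must be >= 0, got {self.alpha!r}")
        if not self.K > 0.0:
            raise ConfigurationError(f"K must be > 0, got {self.K!r}")
        if not self.total_mcs >= 1:
            raise ConfigurationError(f"total_mcs must be >= 1, got {self.total_mcs!r}")
        if not 1 <= self.avg_window <= self.total_mcs:
            raise ConfigurationError(
                f"avg_window must lie in [1, total_mcs], got {self.avg_window!r}"
            )
        if not self.stationarity_tol > 0.0:
            raise ConfigurationError(
                f"stationarity_tol must be > 0, got {self.stationarity_tol!r}"
            )
        if self.extension_block is not None and not self.extension_block >= 1:
            raise ConfigurationError(
                f"extension_block must be >= 1, got {self.extension_block!r}"
            )
        if not self.max_extensions >= 0:
            raise ConfigurationError(f"max_extensions must be >= 0, got {self.max_extensions!r}")
        if not self.n_replicates >= 1:
            raise ConfigurationError(f"n_replicates must be >= 1, got {self.n_replicates!r}")
        if any(t < 0 for t in self.snapshot_times):
            raise ConfigurationError(f"snapshot_times must be >= 0, got {self.snapshot_times!r}")

    @property
    def n_sites(self) -> int:
        return self.L * self.L

    @property
    def effective_extension_block(self) -> int:
        return self.avg_window if self.extension_block is None else self.extension_block

    def with_(self, **kwargs) -> "SimulationParams":
        """Return a copy with the given fields replaced (validated)."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PayoffMatrix:
    """Row player's payoff: R for C-C, S for C-D, T for D-C, P for D-D."""

    R: float = 1.0
    T: float = 1.1
    P: float = 0.0
    S: float = 0.0

    @classmethod
    def weak_pd(cls, b: float) -> "PayoffMatrix":
        """Weak prisoner's dilemma: T = b, R = 1, P = S = 0."""
        if b < 1.0:
            raise ConfigurationError(f"temptation b must be >= 1, got {b!r}")
        return cls(R=1.0, T=float(b), P=0.0, S=0.0)

    def as_array(self) -> np.ndarray:
        """2x2 lookup ``M[s_row, s_col]`` with strategy coding D=0, C=1."""
        return np.array([[self.P, self.T], [self.S, self.R]], dtype=np.float64)


def neighbor_sites(L: int, row: int, col: int) -> list[tuple[int, int]]:
    """Von Neumann neighbours of (row, col) on the torus, ordered up/down/left/right."""
    return [
        ((row - 1) % L, col),
        ((row + 1) % L, col),
        (row, (col - 1) % L),
        (row, (col + 1) % L),
    ]


def neighbor_indices(L: int) -> np.ndarray:
    """Flat (L*L, 4) neighbour index table, row-major sites, order up/down/left/right."""
    idx = np.arange(L * L).reshape(L, L)
    up = np.roll(idx, 1, axis=0)
    down = np.roll(idx, -1, axis=0)
    left = np.roll(idx, 1, axis=1)
    right = np.roll(idx, -1, axis=1)
    return np.stack([up, down, left, right], axis=-1).reshape(L * L, 4).astype(np.int64)


def environment_field(h_field: np.ndarray) -> np.ndarray:
    """Environment H of every site: mean h over its four torus neighbours."""
    return (
        np.roll(h_field, 1, axis=0)
        + np.roll(h_field, -1, axis=0)
        + np.roll(h_field, 1, axis=1)
        + np.roll(h_field, -1, axis=1)
    ) / 4.0


def environment(h_field: np.ndarray, site: tuple[int, int]) -> float:
    """Environment of one site: mean of the neighbours' h; own h excluded."""
    L = h_field.shape[0]
    r, c = site
    if not (0 <= r < L and 0 <= c < h_field.shape[1]):
        raise IndexError(f"site {site!r} out of bounds for {h_field.shape} lattice")
    total = 0.0
    for rr, cc in neighbor_sites(L, r, c):
        total += h_field[rr, cc]
    return total / 4.0


class LatticeState:
    """Mutable lattice configuration: strategies plus quenched h and H fields.

    Strategies are coded D=0, C=1 in an int8 grid.  ``h_field`` and
    ``env_field`` are drawn once and never change during a run.
    """

    __slots__ = ("strategies", "h_field", "env_field", "L", "_nbr")

    def __init__(self, strategies: np.ndarray, h_field: np.ndarray) -> None:
        strategies = np.ascontiguousarray(strategies, dtype=np.int8)
        h_field = np.ascontiguousarray(h_field, dtype=np.float64)
        if strategies.ndim != 2 or strategies.shape[0] != strategies.shape[1]:
            raise ConfigurationError(f"strategies must be square, got shape {strategies.shape}")
        if h_field.shape != strategies.shape:
            raise ConfigurationError(
                f"h_field shape {h_field.shape} does not match strategies {strategies.shape}"
            )
        self.strategies = strategies
        self.h_field = h_field
        self.env_field = environment_field(h_field)
        self.L = strategies.shape[0]
        self._nbr: Optional[np.ndarray] = None

    @property
    def neighbor_table(self) -> np.ndarray:
        if self._nbr is None:
            self._nbr = neighbor_indices(self.L)
        return self._nbr

    def rho_c(self) -> float:
        """Current cooperator fraction."""
        return float(self.strategies.sum()) / self.strategies.size

    def n_cooperators(self) -> int:
        return int(self.strategies.sum())

    def copy(self) -> "LatticeState":
        return LatticeState(self.strategies.copy(), self.h_field)


def init_lattice(
    params: SimulationParams,
    rng: np.random.Generator,
    h_field: Optional[np.ndarray] = None,
) -> LatticeState:
    """Random initial condition: C/D with equal probability, h uniform on the grid.

    Draw order is fixed (strategies first, then h) so a seeded generator
    reproduces the lattice exactly.  ``h_field`` may be supplied to share
    one quenched field across replicates.
    """
    L = params.L
    strategies = rng.integers(0, 2, size=(L, L), dtype=np.int8)
    if h_field is None:
        h_field = H_LEVELS[rng.integers(0, len(H_LEVELS), size=(L, L))]
    else:
        h_field = np.asarray(h_field, dtype=np.float64)
        if h_field.shape != (L, L):
            raise ConfigurationError(
                f"h_field shape {h_field.shape} does not match L={L}"
            )
    return LatticeState(strategies, h_field)


def game_payoff(state: LatticeState, site: tuple[int, int], payoffs: PayoffMatrix) -> float:
    """Payoff of one site from playing the game with its four neighbours.

    Computed fresh from the current strategies; nothing is accumulated
    across steps.  Summation follows the fixed neighbour order so results
    are bit-reproducible.
    """
    r, c = site
    if not (0 <= r < state.L and 0 <= c < state.L):
        raise IndexError(f"site {site!r} out of bounds for L={state.L}")
    M = payoffs.as_array()
    s = state.strategies
    total = 0.0
    for rr, cc in neighbor_sites(state.L, r, c):
        total += M[s[r, c], s[rr, cc]]
    return total


def fitness(payoff: float, env: float, u: float) -> float:
    """Convex combination of game payoff and environment: (1-u)*payoff + u*env."""
    if not 0.0 <= u <= 1.0:
        raise ConfigurationError(f"u must lie in [0, 1], got {u!r}")
    return (1.0 - u) * payoff + u * env


@dataclass
class RunResult:
    """Outcome of a single seeded run.

    ``rho_trajectory[t]`` is the cooperator fraction after MCS ``t``
    (entry 0 is the initial condition), ``rho_equilibrium`` the mean over
    the final ``avg_window`` entries, and ``snapshots`` maps MCS indices
    to copies of the strategy grid.
    """

    rho_trajectory: np.ndarray
    rho_equilibrium: float
    mcs_executed: int
    stationary: bool
    snapshots: dict[int, np.ndarray]
    seed: int
    h_field: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        traj = np.asarray(self.rho_trajectory, dtype=np.float64)
        if traj.min() < 0.0 or traj.max() > 1.0:
            raise ValueError("cooperator fractions must lie in [0, 1]")
        self.rho_trajectory = traj
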