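# Methods

## Model

The population occupies the `L x L` square lattice with periodic
boundaries; every site `x` interacts with its four von Neumann
neighbours (`k = 4`). Each site carries

* a strategy `s_x ∈ {C, D}`, initialized C or D with probability 1/2;
* a quenched heterogeneity value `h_x`, drawn once per run uniformly
  from the 41 discrete levels `{0.0, 0.1, ..., 4.0}` (both endpoints
  included) and never updated;
* an environment value `H_x`, the arithmetic mean of the four
  neighbours' `h` (the site's own `h` is excluded). Because `h` is
  quenched, `H` is quenched too.

The game is the weak prisoner's dilemma: `T = b ≥ 1`, `R = 1`,
`P = S = 0`, so the temptation `b` is the single dilemma-strength
parameter. A site's payoff `P_x` is the sum over its four neighbours of
the row-player payoff, recomputed from the instantaneous configuration
whenever it is needed (no payoff memory). Fitness mixes game payoff and
environment linearly,

```
F_x = (1 - u) P_x + u H_x ,     u ∈ [0, 1],
```

so `u = 0` recovers the traditional spatial game and `u = 1` decouples
the dynamics from the game entirely.

One elementary update: pick a focal site `x` uniformly at random;
draw a model neighbour `y` with the preference-selection probability

```
Ω_y = exp(α h_y) / Σ_{z ∈ N(x)} exp(α h_z) ,    α ≥ 0,
```

(`α = 0` is uniform random choice; the softmax is evaluated with a
max-shift so arbitrarily large `α` cannot overflow); then `x` adopts
`s_y` with the Fermi probability

```
W(y → x) = 1 / (1 + exp((F_x - F_y) / K)) ,
```

with noise amplitude `K = 0.1` throughout. One full Monte Carlo step
(MCS) is `L²` elementary updates with independent uniform focal draws
(asynchronous, random sequential order), so every player updates once
on average. The focal player is never its own imitation candidate, and
the adoption draw is made even when `s_x = s_y` so that the consumed
random stream does not depend on the configuration.

### Reading of the selection and environment rules

Two printed forms of the model equations are internally inconsistent
(the environment and selection sums are written over a constant index);
we adopt the readings that match their verbal definitions: `H_x`
averages the *neighbours'* `h`, and the selection weight uses the
*neighbour's own* `h_y`. We checked the main alternative readings
empirically: taking `H_x = h_x` (the literal degenerate form) sustains
near-full cooperation at `α = 0, u = 0.5, b = 1.05`, where the model is
documented to lose cooperators entirely, and weighting selection by the
neighbour's environment `H_y` depresses cooperation in the high-`u`
regime; both were rejected.

## Measurement protocol

The headline observable is the cooperator fraction `ρ_c`. A run
executes `total_mcs` sweeps and estimates the equilibrium value as the
mean of `ρ_c` over the final `avg_window` sweeps. Stationarity is
operationalized as the absolute difference between the means of the
last two non-overlapping `avg_window` windows being strictly below
`stationarity_tol = 10⁻²`; when the check fails the run is extended by
`extension_block` sweeps (default: one window) and rechecked, up to
`max_extensions` times, after which the run is flagged non-stationary
but still averaged. All-C and all-D are absorbing; once reached, the
remaining trajectory is filled with the constant value without further
sweeps.

Ensembles run `n_replicates` independent replicates, each with its own
lattice, initial condition and freshly drawn `h` field (a switch allows
sharing one field), and report the replicate mean and standard
deviation of the equilibrium `ρ_c`. Child seeds derive from the master
seed by a counter-based scheme (numpy `SeedSequence(master, index)`),
so replicates are exchangeable and could run in parallel without
changing results. Sweep grid points hash the master seed together with
the axis *values*, so extending a grid never perturbs existing points.

### Problem sizes

The full protocol uses `L = 100`, `6 × 10⁴` MCS averaging the last
`10⁴`, and 40 replicates; these are the package defaults and the CLI's
defaults. Tests and the acceptance script use a desk-scale protocol
(`desk_scale_params`): `L = 50`, `7 × 10³` MCS averaging the last
`2 × 10³`, 5–20 replicates depending on the scenario. We verified at
several parameter points that `L = 50` and `L = 100` equilibria agree
within replicate noise. At desk scale the `10⁻²` fluctuation threshold
— calibrated for `10⁴`-sweep windows on `10⁴` sites — sits at the
margin of the naturally larger window-mean fluctuations, so the
desk-scale protocol caps extensions at 2; equilibrium estimates are
unaffected beyond sampling noise.

## Numerical choices

* Strategies are coded D=0 / C=1 in `int8`; payoffs use a 2×2 lookup
  table summed in the fixed neighbour order (up, down, left, right) so
  floating-point results are order-stable.
* Random numbers: one numpy `PCG64` generator per run. Each elementary
  update consumes exactly three uniforms in a fixed order (focal,
  neighbour, adoption). The compiled sweep kernel (numba) receives the
  pre-drawn uniforms and replays exactly the stream the pure-Python
  reference step would consume; the two paths are bit-identical, which
  is tested directly.
* Neighbour selection inverts the per-site cumulative distribution with
  a strict `<` comparison; the quenched selection table is computed
  once per run.
* The Fermi exponent never overflows for model fitness scales
  (`|ΔF|/K ≲ 10²`); for out-of-range inputs the Python path maps an
  `exp` overflow to adoption probability 0, matching the kernel's
  `inf` arithmetic.
* Equilibrium means use the trajectory entries after MCS 0; entry 0
  stores the initial condition.

## Oracle

The test oracle recomputes the single-update flip probability of a
frozen configuration in closed form — `Σ_y Ω_y W(y→x)` over
opposite-strategy neighbours — from a straight-line implementation that
shares no code with the kernel, plus a whole-lattice one-step flip
distribution for small lattices. Monte Carlo flip frequencies from the
kernel are required to agree within four binomial standard deviations.

## What the simulations show and do not show

The desk-scale experiments reproduce: extinction of cooperators in the
traditional game at `b = 1.05`; the exact `b`-independence and
`ρ_c ≈ 0.5` neutrality at `u = 1` (at `u = 1` the payoff matrix drops
out of the fitness, so runs with identical seeds coincide bit for bit
across `b`); the rise of cooperation with `u` at `α = 0` peaking near
`ρ_c ≈ 0.55–0.6`; the bell-shaped `α` dependence at `u = 0.5` with the
optimum in `α ∈ [2, 6]`; monotone suppression of cooperation by `b`;
and the three-phase structure (extinction / coexistence / dominance) of
the `b–u` plane at `α = 3`.

Two quantitative levels reported for the original experiments did not
reproduce under this implementation at either `L = 50` or `L = 100`,
with runs up to `6 × 10⁴` MCS: cooperation at `u = 0.8, α = 3` reaches
`ρ_c ≈ 0.46–0.49` at `b = 1.3` rather than exceeding 0.8, and the
`α = 0` u-sweep peaks at `u ≈ 0.8–0.9` rather than 0.7. The
acceptance script reports the computed values as-is. A possible source
is the normalization of the environment term (mean versus sum of
neighbour `h`, which rescales the effective `u` axis), but the adopted
mean reading follows the model's explicit definition.

## Limitations

* Square lattice with `k = 4` only; no other graphs, no coevolution of
  `h`, no synchronous or best-takes-over dynamics.
* The stationarity diagnostic is the window-mean criterion only; no
  autocorrelation-time estimation.
* Snapshot "clustering" is quantified by the same-strategy
  nearest-neighbour bond fraction, a deliberately simple statistic.
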