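# Methods

## Model

A haploid population of fixed size `N` contains `i` specialists and `N − i`
generalists.  Per replacement event one individual reproduces (chosen
proportionally to fitness) and one is removed uniformly; the specialist
count moves by at most one.  The culture of the population occupies one of
`k` discrete states; per event it moves `c → c'` with probability
`P(c'|i,c)` that may depend on the composition `i` (level dependence).
Biological and cultural moves are treated as separate events within one
step, so the joint kernel factorises,

    P(j, c' | i, c) = P(j | i, c) · P(c' | i, c),

with the cultural factor conditioned on the *pre-replacement* count `i`.
The same convention is applied in the solver and the simulator, so the two
routes target the identical chain.

In the two-state language family, specialists carry advantage `+φ` while
culture is in their preferred state and `−φ` otherwise, generalist fitness
is normalised to 1, and the cultural kernel is

    P(+|−) = (η/N)·π(i/N),   P(−|+) = (η/N)·(1 − π(i/N)),

with the amplification curve
`π(x) = β(1+x)^α/((1+x)^α + (1−x)^α) + (1−β)/2`.  `π` is monotone
non-decreasing, `π(0) = 1/2` (with no specialists the states are
equivalent) and `π(1) = (1+β)/2`.

## Parameters

| parameter | meaning | units | default | notes |
|---|---|---|---|---|
| `N` | population size | individuals | — | ≥ 2; headline analyses use 100–15000, bracketing estimated ancestral group sizes (~600–13000) |
| `φ` | specialist fitness difference | dimensionless | — | `|φ| < 1`; sweeps use 0–0.3, with 0.1 as the representative small advantage |
| `η` | rate of cultural change | expected switch opportunities per generation | 0.1 | per-event switch factor is `η/N`; `0 ≤ η ≤ N`.  One generation = `N` replacement events (the standard Moran convention; needed to put `η` and reported times on the same scale) |
| `α` | amplification steepness | dimensionless | 1 | `> 0`; 1 = proportional influence of specialists on culture |
| `β` | amplification ceiling | dimensionless | 1 | fraction of time in the preferred state at `x = 1` is `(1+β)/2`; `β = 0` makes culture blind to the population |
| start state | initial cultural state | — | `+` | the per-state columns of every result expose the alternative start |

`η` is taken *exactly* as the per-event factor `η/N` in the kernel above.
An informal reading ("culture changes once every `1/η` generations") would
put the all-generalist residence time at `1/η` generations, whereas the
kernel gives `2/η` (each direction switches at rate `η/2` when `π = 1/2`).
We follow the kernel: it is the formal definition, and a numerical
cross-check showed that rescaling `η` to match the informal gloss moves all
of the model's characteristic fold-changes *away* from their published
values while the literal kernel reproduces them.

## Solvers

First-step analysis gives block-tridiagonal linear systems for the fixation
probabilities `ε` (boundaries `ε⃗_0 = 0`, `ε⃗_N = 1`) and the ε-weighted
times `τ` (right-hand side `−ε⃗_i`, boundaries `τ⃗_0 = τ⃗_N = 0`);
conditional times are `t = τ/ε`.  Two independent routes are implemented:

- **block-Thomas** (default): forward elimination over levels with dense
  `k×k` sub-solves, the natural scaling-up of the scalar Thomas algorithm;
- **sparse**: assembly of the `(N−1)k` system in BSR form and a SuperLU
  factorisation.

The systems are weakly diagonally dominant (row sums of the interior
operator vanish), so no pivoting pathologies arise, but every solve is
verified against the residual of the original recurrence:
`‖r‖∞ / max(1, ‖x‖∞) < 1e-10`.  The residual is *relative* because `τ`
grows like `N²` replacement events (≈ 2·10⁸ at `N = 15000`), which puts an
absolute 1e-10 beyond double precision; for the probability systems
(`‖x‖∞ ≤ 1`) the criterion is effectively absolute.  The tests additionally
require the two routes to agree to 1e-10 and to match a dense
fundamental-matrix computation on small state spaces.

Numerical conventions: conditional times where `ε < 1e-14` are reported as
NaN (missing) rather than as huge ratios; times default to generations
(steps/`N`) with `"steps"` available everywhere; the classic baseline's
closed form `ε_i = (1 − r^{−i})/(1 − r^{−N})`, `r = 1 + f`, is evaluated in
a factored log-space form so deleterious variants at large `N` underflow
gracefully to 0 instead of overflowing.

## Simulator

The Monte Carlo estimator advances all replicates synchronously; per sweep
it draws one uniform vector for the biological move (tested against the
cumulative `(p_down, p_stay, p_up)`) and then one for the cultural move
(cumulative kernel row at the pre-replacement count) — two draws per event
in a fixed order, so a seed fully determines every trajectory.  Replicates
stop at `i ∈ {0, N}` or at `max_steps` (default 10⁹ events); capped runs
are reported as censored, never dropped, and excluded only from the time
statistics.  The fixation-probability interval is the Wilson score interval
at 99%; the conditional-time interval is the normal approximation
`mean ± z₀.₉₉₅·s/√n` over fixed runs.  These choices are fixed so that
"solver inside the 99% interval" is a stable acceptance contract.

The simulator emulates exactly the abstractions of the chain — no agent
heterogeneity, no mutation, recombination or variable population size — so
agreement between simulator and solver validates the linear algebra, not
the realism of the model.  What passing tests show about real populations
is therefore limited to what the Moran-with-culture abstraction captures:
in particular, linguistic diversity within a population, overlapping
cultural variants, and asymmetric variant fitness are all outside it
(generic fitness/kernel hooks exist, but no claims are made for them).

## Headline quantities and problem sizes

The package's characteristic outputs are fold-changes of the coupled model
against the classic constant-advantage baseline at matched `N` and `f = φ`,
from a single mutant with culture starting preferred:

- `N = 500, η = 0.1, α = β = 1`: probability ratio 0.364 (≈ one third);
- `N = 1500, η = 0.1, β = 0` (amplification absent): probability reduced
  7.48-fold, conditional time increased 1.97-fold;
- `N = 15000, η = 0.5, α = β = 1`: conditional time increased 2.20-fold;
  the probability reduction computes to 15.3-fold.

On "no amplification": the two-state family admits two readings — `α = β =
1` (proportional coupling) and `β = 0` (no coupling at all).  Only `β = 0`
reproduces the 8-fold/2-fold pair above, so that is the setting used for
it; the proportional-coupling setting at the same `N, η` gives 3.4-fold /
1.2-fold.  These are the parameter attributions recorded in the
acceptance script.

Test problem sizes were chosen so each check runs in seconds: dense-oracle
comparisons at `N ≤ 6`, Monte Carlo cross-checks at `N = 20` with 10⁵
replicates, monotonicity grids at `N ≤ 1500`, and the large-population
solve at `N = 15000` (a ~30k-unknown banded system, well under a second
per solve).

## Known limitations

- Eq-level exactness is only as good as the factorisation assumption
  (biological and cultural moves per event are conditionally independent
  given `(i, c)`); kernels with within-event interaction are out of scope.
- The amplification family is one representative parametric curve; other
  monotone curves through `(0, 1/2)` can be supplied as custom kernels but
  have no built-in sweep.
- Quasi-stationary behaviour of the cultural marginal, loss-conditioned
  absorption times, and asymmetric-fitness variants are not analysed.
- For strongly deleterious invaders at large `N`, `ε` underflows and the
  corresponding conditional times are reported missing by design.
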