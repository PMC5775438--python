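"""Monte Carlo simulation of the coupled chain.

An independent stochastic oracle for the exact solver: replicate trajectories
of the joint (composition, culture) chain are run to absorption and the
fixation fraction and conditional fixation times are estimated with
confidence intervals.

Randomness contract: every replacement event consumes exactly two uniform
draws from the generator, in fixed order — first the biological move
(compared against the cumulative ``(p_down, p_stay, p_up)``), then the
cultural move (compared against the cumulative kernel row, conditioned on
the pre-replacement count).  The batch estimator advances all live
replicates synchronously and draws one biological vector then one cultural
vector per sweep, so results are reproducible for a given seed, replicate
count and parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .core_model import (
    CompositionState,
    CoupledModel,
    ParameterError,
    _bio_prob_arrays,
)

__all__ = ["SimulationEstimate", "step", "run_to_fixation", "estimate_fixation"]

DEFAULT_MAX_STEPS = 10**9
_Z99 = float(norm.ppf(0.995))  # two-sided 99%


@dataclass
class SimulationEstimate:
    """Monte Carlo fixation estimates with 99% confidence intervals.

    ``p_hat`` is the fixation fraction with a Wilson score interval
    ``p_ci``; ``t_hat`` is the mean conditional fixation time over fixed
    runs (units as requested) with a normal-approximation interval
    ``t_ci``.  Censored runs (those hitting ``max_steps``) are counted in
    ``n_censored`` and excluded from the time statistics but kept in the
    denominator of ``p_hat`` (a censored run has not fixed).
    """

    n_runs: int
    n_fixed: int
    p_hat: float
    p_ci: tuple
    t_hat: float
    t_ci: tuple
    units: str
    seed: int
    max_steps: int
    n_censored: int


def _tables(model: CoupledModel):
    """Per-model cached (p_down, p_stay, cumulative kernel) lookup tables."""
    cached = model.__dict__.get("_sim_tables")
    if cached is None:
        p_down, p_stay, _ = _bio_prob_arrays(model)
        cached = (p_down, p_stay, np.cumsum(model.cultural_kernel, axis=2))
        model.__dict__["_sim_tables"] = cached
    return cached


def step(state: CompositionState, model: CoupledModel, rng: np.random.Generator) -> CompositionState:
    """One replacement event from an interior state; absorbing states pass through."""
    i = state.i
    if i == 0 or i == model.N:
        return state
    c = model.state_index(state.c)
    p_down, p_stay, kernel_cum = _tables(model)
    u_bio = rng.random()
    if u_bio < p_down[i, c]:
        j = i - 1
    elif u_bio < p_down[i, c] + p_stay[i, c]:
        j = i
    else:
        j = i + 1
    u_cul = rng.random()
    c_new = int(np.searchsorted(kernel_cum[i, c], u_cul, side="right"))
    c_new = min(c_new, model.k - 1)  # guard against cumsum rounding at 1.0
    return CompositionState(i=j, c=model.state_labels[c_new])


def run_to_fixation(
    model: CoupledModel,
    start: CompositionState,
    rng: np.random.Generator,
    max_steps: int = DEFAULT_MAX_STEPS,
):
    """Iterate :func:`step` until absorption or the step cap.

    Returns ``(outcome, steps)`` with outcome one of ``"fixed"`` (all
    specialists), ``"lost"`` (none) or ``"censored"`` (cap reached).
    """
    if max_steps < 1:
        raise ParameterError("max_steps must be >= 1")
    state = start
    for n in range(max_steps + 1):
        if state.i == model.N:
            return "fixed", n
        if state.i == 0:
            return "lost", n
        if n == max_steps:
            break
        state = step(state, model, rng)
    return "censored", max_steps


def estimate_fixation(
    model: CoupledModel,
    start: CompositionState,
    n_runs: int,
    seed: int,
    max_steps: int = DEFAULT_MAX_STEPS,
    units: str = "generations",
) -> SimulationEstimate:
    """Estimate fixation probability and conditional time over replicates.

    All replicates run synchronously in a vectorised sweep (see the module
    docstring for the draw order).  The probability interval is the Wilson
    score interval at 99%; the time interval is mean ± z * s / sqrt(n) over
    fixed runs.
    """
    if n_runs < 1:
        raise ParameterError("n_runs must be >= 1")
    if units not in ("generations", "steps"):
        raise ParameterError(f"units must be 'generations' or 'steps', got {units!r}")
    if not 0 <= start.i <= model.N:
        raise ParameterError(f"start.i must lie in [0, N], got {start.i}")
    c0 = model.state_index(start.c)
    rng = np.random.default_rng(seed)

    p_down, p_stay, kernel_cum = _tables(model)

    i_cur = np.full(n_runs, start.i, dtype=np.int64)
    c_cur = np.full(n_runs, c0, dtype=np.int64)
    steps = np.zeros(n_runs, dtype=np.int64)
    alive = (i_cur > 0) & (i_cur < model.N)

    n_sweeps = 0
    while alive.any() and n_sweeps < max_steps:
        n_sweeps += 1
        idx = np.nonzero(alive)[0]
        ii, cc = i_cur[idx], c_cur[idx]
        u_bio = rng.random(idx.size)
        down = u_bio < p_down[ii, cc]
        up = u_bio >= p_down[ii, cc] + p_stay[ii, cc]
        u_cul = rng.random(idx.size)
        # Cultural move conditions on the pre-replacement count ii.
        rows = kernel_cum[ii, cc]
        c_new = (u_cul[:, None] >= rows).sum(axis=1)
        np.minimum(c_new, model.k - 1, out=c_new)
        i_cur[idx] = ii - down + up
        c_cur[idx] = c_new
        steps[idx] += 1
        alive[idx] = (i_cur[idx] > 0) & (i_cur[idx] < model.N)

    fixed = i_cur == model.N
    censored = alive
    n_fixed = int(fixed.sum())
    n_censored = int(censored.sum())
    if n_censored == n_runs:
        raise ArithmeticError(
            f"all {n_runs} replicates hit the step cap ({max_steps}); "
            "estimate inconclusive — raise max_steps"
        )

    p_hat = n_fixed / n_runs
    p_ci = _wilson_interval(n_fixed, n_runs, _Z99)

    scale = 1.0 / model.N if units == "generations" else 1.0
    if n_fixed > 0:
        t_fixed = steps[fixed] * scale
        t_hat = float(t_fixed.mean())
        if n_fixed > 1:
            half = _Z99 * float(t_fixed.std(ddof=1)) / np.sqrt(n_fixed)
        else:
            half = np.inf
        t_ci = (t_hat - half, t_hat + half)
    else:
        t_hat, t_ci = float("nan"), (float("nan"), float("nan"))

    return SimulationEstimate(
        n_runs=n_runs,
        n_fixed=n_fixed,
        p_hat=p_hat,
        p_ci=p_ci,
        t_hat=t_hat,
        t_ci=t_ci,
        units=units,
        seed=seed,
        max_steps=max_steps,
        n_censored=n_censored,
    )


def _wilson_interval(successes: int, n: int, z: float):
    p = successes / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))
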