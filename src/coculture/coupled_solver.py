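"""Exact fixation probabilities and times for the coupled chain.

The joint chain on states ``(i, c)`` is block tridiagonal: level ``i`` only
connects to levels ``i - 1``, ``i``, ``i + 1`` through the ``k x k`` blocks
``(M_i, K_i, L_i)``.  First-step analysis gives, for interior levels,

    eps_i = M_i eps_{i-1} + K_i eps_i + L_i eps_{i+1},

with boundary vectors ``eps_0 = 0`` and ``eps_N = 1``, and for the
epsilon-weighted absorption times

    -eps_i = M_i tau_{i-1} + (K_i - I) tau_i + L_i tau_{i+1},

with ``tau_0 = tau_N = 0``.  Conditional fixation times are
``t_{i,c} = tau_{i,c} / eps_{i,c}``.

Two independent solution routes are provided: a block-Thomas forward
elimination with dense ``k x k`` sub-solves, and a general sparse LU
factorisation of the assembled system; they must agree and both are checked
against the residual of the original equations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .classic_moran import EPS_FLOOR, solve_classic
from .core_model import (
    CompositionState,
    CoupledModel,
    LanguageModelParams,
    ParameterError,
    block_arrays,
    build_language_model,
)

__all__ = [
    "FixationResult",
    "solve_fixation_probabilities",
    "solve_fixation_times",
    "solve_model",
    "fixation_summary",
    "culture_effect_ratios",
]

_RESIDUAL_TOL = 1e-10
_METHODS = ("block_thomas", "sparse")


@dataclass
class FixationResult:
    """Fixation probabilities and times over the full ``(i, c)`` grid.

    ``epsilon[i, c]`` is the probability the specialists fix from ``i``
    copies with culture in state ``c``; ``tau`` the epsilon-weighted times;
    ``t_conditional = tau / epsilon`` (NaN where ``epsilon`` is numerically
    zero).  ``units`` applies to the time arrays; ``params_echo`` records
    the generating parameters when the model came from the language family.
    """

    epsilon: np.ndarray
    tau: np.ndarray
    t_conditional: np.ndarray
    units: str
    state_labels: tuple
    params_echo: object = None


def _interior_blocks(model: CoupledModel):
    """Lower, diagonal and upper coefficient blocks of the interior system."""
    M, K, L = block_arrays(model)
    eye = np.eye(model.k)
    lower = M[1:-1]            # level i couples down via M_i
    diag = K[1:-1] - eye       # (K_i - I)
    upper = L[1:-1]            # and up via L_i
    return lower, diag, upper, M, K, L


def _solve_block_thomas(lower, diag, upper, rhs):
    """Block tridiagonal solve by forward elimination / back substitution."""
    n = diag.shape[0]
    c_prime = np.empty_like(upper)
    d_prime = np.empty_like(rhs)
    denom = diag[0]
    c_prime[0] = np.linalg.solve(denom, upper[0])
    d_prime[0] = np.linalg.solve(denom, rhs[0])
    for j in range(1, n):
        denom = diag[j] - lower[j] @ c_prime[j - 1]
        c_prime[j] = np.linalg.solve(denom, upper[j])
        d_prime[j] = np.linalg.solve(denom, rhs[j] - lower[j] @ d_prime[j - 1])
    x = np.empty_like(rhs)
    x[n - 1] = d_prime[n - 1]
    for j in range(n - 2, -1, -1):
        x[j] = d_prime[j] - c_prime[j] @ x[j + 1]
    return x


def _assemble_sparse(lower, diag, upper):
    """Assemble the interior system as a BSR matrix with k x k blocks."""
    n, k, _ = diag.shape
    blocks = []
    indices = []
    indptr = [0]
    for j in range(n):
        if j > 0:
            indices.append(j - 1)
            blocks.append(lower[j])
        indices.append(j)
        blocks.append(diag[j])
        if j < n - 1:
            indices.append(j + 1)
            blocks.append(upper[j])
        indptr.append(len(indices))
    return sp.bsr_matrix(
        (np.array(blocks), np.array(indices), np.array(indptr)),
        shape=(n * k, n * k),
    )


def _solve_sparse(lower, diag, upper, rhs):
    A = _assemble_sparse(lower, diag, upper).tocsc()
    x = spla.splu(A).solve(rhs.reshape(-1))
    return x.reshape(rhs.shape)


def _residual(lower, diag, upper, x, rhs):
    r = np.einsum("nij,nj->ni", diag, x) - rhs
    r[1:] += np.einsum("nij,nj->ni", lower[1:], x[:-1])
    r[:-1] += np.einsum("nij,nj->ni", upper[:-1], x[1:])
    return np.abs(r).max()


def _solve_interior(model: CoupledModel, rhs, method: str, what: str):
    if method not in _METHODS:
        raise ParameterError(f"method must be one of {_METHODS}, got {method!r}")
    lower, diag, upper, *_ = _interior_blocks(model)
    solver = _solve_block_thomas if method == "block_thomas" else _solve_sparse
    try:
        x = solver(lower, diag, upper, rhs)
    except np.linalg.LinAlgError as exc:
        raise ArithmeticError(f"singular system while solving {what}") from exc
    resid = _residual(lower, diag, upper, x, rhs)
    # Relative residual: tau solutions scale like N^2 steps, so an absolute
    # tolerance would be unattainable in double precision at large N.
    resid /= max(1.0, np.abs(x).max())
    if not resid < _RESIDUAL_TOL:
        raise ArithmeticError(
            f"solve for {what} failed the residual check ({resid:.2e})"
        )
    return x


def solve_fixation_probabilities(
    model: CoupledModel, method: str = "block_thomas"
) -> np.ndarray:
    """Fixation probabilities ``epsilon[i, c]`` of the coupled chain.

    Solves the ``(N-1) k`` linear system with boundaries ``eps_0 = 0`` and
    ``eps_N = 1``; entries are clipped only by validation, never adjusted.
    """
    N, k = model.N, model.k
    _, _, _, _, _, L = _interior_blocks(model)
    rhs = np.zeros((N - 1, k))
    rhs[-1] = -L[N - 1] @ np.ones(k)  # boundary term eps_N = 1
    eps_int = _solve_interior(model, rhs, method, "fixation probabilities")
    if eps_int.min() < -1e-9 or eps_int.max() > 1 + 1e-9:
        raise ArithmeticError("fixation probabilities escaped [0, 1]")
    epsilon = np.empty((N + 1, k))
    epsilon[0] = 0.0
    epsilon[1:-1] = eps_int
    epsilon[-1] = 1.0
    return epsilon


def solve_fixation_times(
    model: CoupledModel,
    epsilon: np.ndarray,
    method: str = "block_thomas",
    units: str = "generations",
):
    """Epsilon-weighted and conditional fixation times given ``epsilon``.

    Solves the same block-tridiagonal structure with right-hand side
    ``-eps_i`` and boundaries ``tau_0 = tau_N = 0``; conditional times are
    ``tau / epsilon``, reported as NaN where ``epsilon`` is numerically
    unreachable (below 1e-14) rather than as spurious huge values.
    Times are in replacement-event steps, divided by ``N`` when ``units`` is
    ``"generations"``.
    """
    if units not in ("generations", "steps"):
        raise ParameterError(f"units must be 'generations' or 'steps', got {units!r}")
    N, k = model.N, model.k
    rhs = -np.asarray(epsilon)[1:-1]
    tau_int = _solve_interior(model, rhs, method, "fixation times")
    tau = np.zeros((N + 1, k))
    tau[1:-1] = tau_int
    with np.errstate(divide="ignore", invalid="ignore"):
        t_cond = np.where(epsilon > EPS_FLOOR, tau / epsilon, np.nan)
    t_cond[-1] = 0.0
    if units == "generations":
        tau = tau / N
        t_cond = t_cond / N
    return tau, t_cond


def solve_model(
    model: CoupledModel,
    method: str = "block_thomas",
    units: str = "generations",
    params_echo: object = None,
) -> FixationResult:
    """Solve probabilities and times in one call."""
    epsilon = solve_fixation_probabilities(model, method=method)
    tau, t_cond = solve_fixation_times(model, epsilon, method=method, units=units)
    return FixationResult(
        epsilon=epsilon,
        tau=tau,
        t_conditional=t_cond,
        units=units,
        state_labels=model.state_labels,
        params_echo=params_echo,
    )


def fixation_summary(
    model: CoupledModel,
    start: CompositionState,
    method: str = "block_thomas",
    units: str = "generations",
):
    """``(epsilon, t)`` at a start state — typically a single mutant, ``i = 1``."""
    if not 0 <= start.i <= model.N:
        raise ParameterError(f"start.i must lie in [0, N], got {start.i}")
    c = model.state_index(start.c)
    if start.i == model.N:
        return 1.0, 0.0
    if start.i == 0:
        return 0.0, float("nan")
    res = solve_model(model, method=method, units=units)
    return float(res.epsilon[start.i, c]), float(res.t_conditional[start.i, c])


def culture_effect_ratios(
    params: LanguageModelParams,
    start_i: int = 1,
    method: str = "block_thomas",
):
    """How much co-evolving culture changes a single mutant's fate.

    Returns ``(prob_ratio, time_ratio)``: the coupled model's fixation
    probability and conditional time from ``(start_i, start_state)``, each
    divided by the classic constant-advantage baseline with ``f = phi`` at
    the same ``N`` (matched parameters, no culture).  Both times are in the
    same units so the ratio is unit-free.
    """
    model = build_language_model(params)
    res = solve_model(model, method=method, units="steps", params_echo=params)
    c = model.state_index(params.start_state)
    classic = solve_classic(params.N, params.phi, units="steps")
    prob_ratio = res.epsilon[start_i, c] / classic.epsilon[start_i]
    time_ratio = res.t_conditional[start_i, c] / classic.t_conditional[start_i]
    return float(prob_ratio), float(time_ratio)
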