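"""The culture-free Moran baseline: fixation probabilities and times.

A birth-death chain on the specialist count ``i = 0..N`` with a constant
fitness advantage ``f``.  Provides the closed-form fixation probability, a
numerically solved version of the first-step recurrences (tridiagonal linear
systems), and conditional fixation times; this is the "without culture"
reference against which the coupled model is compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .core_model import ParameterError, moran_transition_probs

__all__ = [
    "ClassicMoranModel",
    "ClassicResult",
    "moran_transition_probs",
    "closed_form_fixation",
    "solve_classic",
]

_RESIDUAL_TOL = 1e-10
#: Fixation probabilities below this are treated as numerically unreachable
#: when forming conditional times.
EPS_FLOOR = 1e-14


@dataclass(frozen=True)
class ClassicMoranModel:
    """Population size ``N`` and constant advantage ``f`` (``r = 1 + f``)."""

    N: int
    f: float

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ParameterError(f"N must be >= 2, got {self.N}")
        if not 1.0 + self.f > 0:
            raise ParameterError(f"fitness ratio 1 + f must be positive, got f={self.f}")


@dataclass
class ClassicResult:
    """Per-``i`` fixation probabilities and times of the classic chain.

    ``epsilon[i]`` is the fixation probability from ``i`` specialists,
    ``tau[i]`` the epsilon-weighted time, and
    ``t_conditional[i] = tau[i] / epsilon[i]`` the mean time to fixation
    conditional on fixation (NaN where ``epsilon`` is numerically zero).
    ``units`` is ``"generations"`` (steps / N) or ``"steps"``.
    """

    N: int
    f: float
    epsilon: np.ndarray
    tau: np.ndarray
    t_conditional: np.ndarray
    units: str


def closed_form_fixation(N: int, f: float, i: int = 1) -> float:
    """Closed-form fixation probability of the constant-advantage chain.

    With fitness ratio ``r = 1 + f`` the per-step down/up ratio is constant,
    ``mu_i / lambda_i = 1/r``, so the textbook birth-death result applies:
    ``eps_i = (1 - r^{-i}) / (1 - r^{-N})``, with the neutral limit ``i / N``.
    Evaluated in a log-space form that is overflow-safe for large ``N`` and
    ``r < 1``.
    """
    ClassicMoranModel(N, f)
    if not 0 <= i <= N:
        raise ParameterError(f"i must lie in [0, N], got {i}")
    lr = np.log1p(f)
    if lr == 0.0:
        return i / N
    if lr > 0:
        # r > 1: r^{-i} decays, the direct form is safe.
        return float(np.expm1(-i * lr) / np.expm1(-N * lr))
    # r < 1: factor out the growing exponential before dividing.
    # eps = e^{(N-i) lr} * (1 - e^{i lr}) / (1 - e^{N lr}); all terms in (0, 1].
    return float(
        np.exp((N - i) * lr) * (-np.expm1(i * lr)) / (-np.expm1(N * lr))
    )


def solve_classic(N: int, f: float, units: str = "generations") -> ClassicResult:
    """Solve the fixation recurrences of the classic chain numerically.

    Fixation probabilities satisfy the first-step relation
    ``eps_i = mu_i eps_{i-1} + (1 - mu_i - lambda_i) eps_i + lambda_i eps_{i+1}``
    with ``eps_0 = 0`` and ``eps_N = 1``; the epsilon-weighted times satisfy
    the analogous system with right-hand side ``-eps_i`` and boundaries
    ``tau_0 = tau_N = 0``.  Both are tridiagonal and solved by banded
    elimination; residuals are checked to 1e-10.
    """
    model = ClassicMoranModel(N, f)
    if units not in ("generations", "steps"):
        raise ParameterError(f"units must be 'generations' or 'steps', got {units!r}")
    idx = np.arange(1, N)
    probs = np.array([moran_transition_probs(i, N, f) for i in idx])
    mu, lam = probs[:, 0], probs[:, 2]

    # System A eps = b over interior i, A = tridiag(mu, -(mu+lam), lam).
    n = N - 1
    ab = np.zeros((3, n))
    ab[0, 1:] = lam[:-1]          # superdiagonal
    ab[1, :] = -(mu + lam)        # diagonal
    ab[2, :-1] = mu[1:]           # subdiagonal
    b = np.zeros(n)
    b[-1] = -lam[-1]              # boundary eps_N = 1
    eps_int = solve_banded((1, 1), ab, b)
    _check_residual(ab, eps_int, b, "fixation probabilities")

    b_tau = -eps_int
    tau_int = solve_banded((1, 1), ab, b_tau)
    _check_residual(ab, tau_int, b_tau, "fixation times")

    epsilon = np.concatenate([[0.0], eps_int, [1.0]])
    tau = np.concatenate([[0.0], tau_int, [0.0]])
    with np.errstate(divide="ignore", invalid="ignore"):
        t_cond = np.where(epsilon > EPS_FLOOR, tau / epsilon, np.nan)
    t_cond[N] = 0.0
    if units == "generations":
        tau = tau / N
        t_cond = t_cond / N
    return ClassicResult(
        N=N, f=model.f, epsilon=epsilon, tau=tau, t_conditional=t_cond, units=units
    )


def _check_residual(ab: np.ndarray, x: np.ndarray, b: np.ndarray, what: str) -> None:
    n = len(x)
    r = ab[1] * x
    r[:-1] += ab[0, 1:] * x[1:]
    r[1:] += ab[2, :-1] * x[:-1]
    resid = np.abs(r - b).max() if n else 0.0
    # Relative residual: tau grows like N^2 steps, beyond an absolute 1e-10.
    resid /= max(1.0, np.abs(x).max())
    if not resid < _RESIDUAL_TOL:
        raise ArithmeticError(
            f"tridiagonal solve for {what} failed the residual check "
            f"({resid:.2e} >= {_RESIDUAL_TOL})"
        )
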