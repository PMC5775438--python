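"""Model parameterisations and transition structure of the coupled chain.

The population is a fixed-size Moran process with two biological types —
*specialists*, who acquire one cultural variant (the "preferred" state, ``+``)
more easily but the other (``-``) less easily, and *generalists*, who are
indifferent.  The culture of the population occupies one of ``k`` discrete
states and evolves alongside the population; crucially its transition
probabilities may depend on the biological composition (*level dependence*),
which is the feedback loop between the two inheritance streams.

This module defines the parameter containers, the per-composition biological
and cultural transition probabilities of the two-state language model, and the
``k x k`` block matrices from which the full ``(N+1)k``-state chain is
assembled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PREFERRED",
    "OTHER",
    "LanguageModelParams",
    "CompositionState",
    "CoupledModel",
    "BlockTriplet",
    "amplification_pi",
    "biological_transition_probs",
    "cultural_transition_matrix",
    "build_language_model",
    "build_custom_model",
    "build_blocks",
]

#: Label of the cultural state the specialists are better at acquiring.
PREFERRED = "+"
#: Label of the state where specialists are at a disadvantage.
OTHER = "-"

_ROW_TOL = 1e-12


class ParameterError(ValueError):
    """A model parameter is outside its admissible domain."""


@dataclass(frozen=True)
class LanguageModelParams:
    """Scalars of the two-state specialist/generalist language model.

    Parameters
    ----------
    N : int
        Population size (number of individuals), at least 2.
    phi : float
        Fitness difference of specialists, ``|phi| < 1``.  Specialists have
        fitness ``1 + phi`` relative to generalists while culture sits in
        their preferred state and ``1 - phi`` in the other state.
    eta : float
        Rate of cultural change.  The per-replacement-event switch
        probability carries a factor ``eta / N``, so ``eta`` is the expected
        number of switch opportunities per generation (one generation =
        ``N`` replacement events).  Must satisfy ``0 <= eta <= N``.
    alpha : float
        Amplification steepness (> 0).  ``alpha > 1`` means a few specialists
        already tilt cultural change strongly toward their preferred state.
    beta : float
        Amplification ceiling in ``[0, 1]``: the excess fraction of time
        culture spends in the preferred state once the population is all
        specialists is ``beta / 2`` (i.e. the fraction is ``(1 + beta) / 2``).
    start_state : str
        Initial cultural state label, ``"+"`` or ``"-"``.
    """

    N: int
    phi: float
    eta: float
    alpha: float = 1.0
    beta: float = 1.0
    start_state: str = PREFERRED

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ParameterError(f"population size N must be >= 2, got {self.N}")
        if not abs(self.phi) < 1:
            raise ParameterError(f"|phi| must be < 1, got {self.phi}")
        if not 0 <= self.eta <= self.N:
            raise ParameterError(
                f"eta must lie in [0, N] so eta/N is a probability factor, got {self.eta}"
            )
        if not self.alpha > 0:
            raise ParameterError(f"alpha must be positive, got {self.alpha}")
        if not 0 <= self.beta <= 1:
            raise ParameterError(f"beta must lie in [0, 1], got {self.beta}")
        if self.start_state not in (PREFERRED, OTHER):
            raise ParameterError(
                f"start_state must be {PREFERRED!r} or {OTHER!r}, got {self.start_state!r}"
            )


@dataclass(frozen=True)
class CompositionState:
    """Joint state of the chain: ``i`` specialists and cultural state ``c``."""

    i: int
    c: str


@dataclass
class CoupledModel:
    """A general ``(N+1) * k``-state coupled biological/cultural chain.

    Attributes
    ----------
    N : int
        Population size.
    state_labels : tuple of str
        The ``k`` cultural state labels, in matrix order.
    advantage : ndarray, shape (N+1, k)
        Fitness advantage ``f`` of the indexed (specialist) type at each
        composition ``i`` and cultural state ``c`` (``f = f_s - f_g`` with
        generalist fitness normalised to 1); the birth-death probabilities
        use the classic Moran form with this ``f``.
    cultural_kernel : ndarray, shape (N+1, k, k)
        Row-stochastic matrices ``P(c' | i, c)``; entry ``[i, c, c']`` is the
        probability the culture moves from state ``c`` to ``c'`` during a
        replacement event that starts with ``i`` specialists.
    """

    N: int
    state_labels: tuple
    advantage: np.ndarray
    cultural_kernel: np.ndarray

    def __post_init__(self) -> None:
        self.state_labels = tuple(self.state_labels)
        k = len(self.state_labels)
        if k < 1:
            raise ParameterError("need at least one cultural state")
        self.advantage = np.asarray(self.advantage, dtype=float)
        self.cultural_kernel = np.asarray(self.cultural_kernel, dtype=float)
        if self.advantage.shape != (self.N + 1, k):
            raise ParameterError(
                f"advantage must have shape {(self.N + 1, k)}, got {self.advantage.shape}"
            )
        if self.cultural_kernel.shape != (self.N + 1, k, k):
            raise ParameterError(
                f"cultural_kernel must have shape {(self.N + 1, k, k)}, "
                f"got {self.cultural_kernel.shape}"
            )
        if np.any(self.cultural_kernel < -_ROW_TOL):
            raise ParameterError("cultural_kernel has negative entries")
        row_sums = self.cultural_kernel.sum(axis=2)
        if not np.allclose(row_sums, 1.0, atol=1e-10, rtol=0):
            worst = np.abs(row_sums - 1.0).max()
            raise ParameterError(
                f"cultural_kernel rows must sum to 1 (worst deviation {worst:.2e})"
            )
        i = np.arange(self.N + 1)[:, None]
        if np.any(self.N + self.advantage * i <= 0):
            raise ParameterError(
                "fitness advantage too negative: denominator N + f*i must stay positive"
            )

    @property
    def k(self) -> int:
        return len(self.state_labels)

    def state_index(self, label: str) -> int:
        try:
            return self.state_labels.index(label)
        except ValueError:
            raise ParameterError(
                f"unknown cultural state {label!r}; labels are {self.state_labels}"
            ) from None


@dataclass(frozen=True)
class BlockTriplet:
    """The three ``k x k`` blocks of one composition level ``i``.

    ``M[c, c']`` is the joint probability of losing one specialist while the
    culture moves ``c -> c'``; ``K`` keeps the count; ``L`` gains one.  For
    interior ``i`` the entries of ``M + K + L`` sum to one per source row.
    """

    i: int
    M: np.ndarray
    K: np.ndarray
    L: np.ndarray


def amplification_pi(x, alpha: float, beta: float):
    """Fraction of time culture spends in the preferred state.

    ``pi(x) = beta * (1+x)^alpha / ((1+x)^alpha + (1-x)^alpha) + (1-beta)/2``
    for a proportion ``x`` of specialists.  ``pi(0) = 1/2`` always (with no
    specialists the two states are equivalent) and ``pi(1) = (1+beta)/2``.
    ``alpha`` controls how steeply a minority of specialists tilts the
    balance; the function is non-decreasing in ``x`` and bounded in
    ``[1/2, 1]``.

    Accepts scalar or array ``x``.
    """
    if not alpha > 0:
        raise ParameterError(f"alpha must be positive, got {alpha}")
    if not 0 <= beta <= 1:
        raise ParameterError(f"beta must lie in [0, 1], got {beta}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ParameterError("x must lie in [0, 1]")
    up = (1.0 + x) ** alpha
    down = (1.0 - x) ** alpha
    out = beta * up / (up + down) + (1.0 - beta) / 2.0
    return out if out.ndim else float(out)


def biological_transition_probs(i: int, N: int, phi: float, state: str):
    """Birth-death probabilities ``(p_down, p_stay, p_up)`` for the language model.

    In the preferred state specialists have advantage ``+phi``; in the other
    state ``-phi``.  Boundaries ``i = 0`` and ``i = N`` are absorbing.
    """
    if state not in (PREFERRED, OTHER):
        raise ParameterError(f"state must be {PREFERRED!r} or {OTHER!r}")
    f = phi if state == PREFERRED else -phi
    return moran_transition_probs(i, N, f)


def moran_transition_probs(i: int, N: int, f: float):
    """Classic Moran birth-death probabilities ``(p_down, p_stay, p_up)``.

    One individual reproduces (selected proportionally to fitness, the
    indexed type having advantage ``f``) and one is removed uniformly:

    ``p_up = (N-i)/N * (1+f) i / (N + f i)``,
    ``p_down = i/N * (N-i) / (N + f i)``,

    and ``p_stay`` complements the pair to one.
    """
    if not 0 <= i <= N:
        raise ParameterError(f"i must lie in [0, N], got {i}")
    denom = N + f * i
    if denom <= 0:
        raise ParameterError("denominator N + f*i must be positive")
    p_up = (N - i) / N * ((1.0 + f) * i) / denom
    p_down = (i / N) * (N - i) / denom
    return p_down, 1.0 - p_up - p_down, p_up


def cultural_transition_matrix(i: int, params: LanguageModelParams) -> np.ndarray:
    """The 2x2 matrix ``P(c' | i, c)`` for the two-state language model.

    Per replacement event the culture switches out of the disfavoured
    direction with probability ``(eta/N) * pi(i/N)`` and out of the preferred
    state with probability ``(eta/N) * (1 - pi(i/N))``; rows (source state
    order ``+``, ``-``) sum to one.
    """
    if not 0 <= i <= params.N:
        raise ParameterError(f"i must lie in [0, N], got {i}")
    pi_x = amplification_pi(i / params.N, params.alpha, params.beta)
    rate = params.eta / params.N
    p_to_plus = rate * pi_x          # from -, toward preferred
    p_to_minus = rate * (1.0 - pi_x)  # from +, away from preferred
    return np.array(
        [[1.0 - p_to_minus, p_to_minus],
         [p_to_plus, 1.0 - p_to_plus]]
    )


def build_language_model(params: LanguageModelParams) -> CoupledModel:
    """Assemble the two-state language model as a :class:`CoupledModel`.

    Specialists carry advantage ``+phi`` while culture is in the preferred
    state and ``-phi`` in the other state (the disadvantage in one state
    equals the advantage in the other); the cultural kernel follows
    :func:`cultural_transition_matrix` at every composition.
    """
    N = params.N
    advantage = np.empty((N + 1, 2))
    advantage[:, 0] = params.phi
    advantage[:, 1] = -params.phi
    x = np.arange(N + 1) / N
    pi_x = amplification_pi(x, params.alpha, params.beta)
    rate = params.eta / N
    kernel = np.empty((N + 1, 2, 2))
    kernel[:, 0, 1] = rate * (1.0 - pi_x)
    kernel[:, 0, 0] = 1.0 - kernel[:, 0, 1]
    kernel[:, 1, 0] = rate * pi_x
    kernel[:, 1, 1] = 1.0 - kernel[:, 1, 0]
    return CoupledModel(
        N=N,
        state_labels=(PREFERRED, OTHER),
        advantage=advantage,
        cultural_kernel=kernel,
    )


def build_custom_model(
    N: int,
    state_labels: Sequence[str],
    advantage: "np.ndarray | Callable[[int, int], float]",
    kernel: "np.ndarray | Callable[[int], np.ndarray]",
) -> CoupledModel:
    """Build a :class:`CoupledModel` from tables or per-composition callables.

    ``advantage`` is either an ``(N+1, k)`` array or a function
    ``(i, c_index) -> f``; ``kernel`` is an ``(N+1, k, k)`` array, a single
    constant ``(k, k)`` matrix, or a function ``i -> (k, k)`` matrix (the
    composition-dependence hook for custom cultural transition graphs).
    """
    labels = tuple(state_labels)
    k = len(labels)
    if callable(advantage):
        adv = np.array(
            [[float(advantage(i, c)) for c in range(k)] for i in range(N + 1)]
        )
    else:
        adv = np.asarray(advantage, dtype=float)
        if adv.shape == (k,):
            adv = np.tile(adv, (N + 1, 1))
    if callable(kernel):
        ker = np.array([np.asarray(kernel(i), dtype=float) for i in range(N + 1)])
    else:
        ker = np.asarray(kernel, dtype=float)
        if ker.shape == (k, k):
            ker = np.tile(ker, (N + 1, 1, 1))
    return CoupledModel(N=N, state_labels=labels, advantage=adv, cultural_kernel=ker)


def _bio_prob_arrays(model: CoupledModel):
    """Vectorised ``(p_down, p_stay, p_up)`` arrays of shape ``(N+1, k)``."""
    N = model.N
    i = np.arange(N + 1, dtype=float)[:, None]
    f = model.advantage
    denom = N + f * i
    p_up = (N - i) / N * (1.0 + f) * i / denom
    p_down = i / N * (N - i) / denom
    return p_down, 1.0 - p_up - p_down, p_up


def build_blocks(model: CoupledModel) -> list[BlockTriplet]:
    """Blocks ``(M_i, K_i, L_i)`` of the block-tridiagonal chain, ``i = 0..N``.

    Biological and cultural moves factorise per event,
    ``P(j, c' | i, c) = P(j | i, c) * P(c' | i, c)``, with the cultural factor
    conditioned on the pre-replacement count ``i``; hence each block is an
    outer scaling of the cultural kernel row by the birth-death probability.
    """
    M, K, L = block_arrays(model)
    return [BlockTriplet(i=i, M=M[i], K=K[i], L=L[i]) for i in range(model.N + 1)]


def block_arrays(model: CoupledModel):
    """Stacked block matrices ``M, K, L`` of shape ``(N+1, k, k)`` each."""
    p_down, p_stay, p_up = _bio_prob_arrays(model)
    ker = model.cultural_kernel
    M = p_down[:, :, None] * ker
    K = p_stay[:, :, None] * ker
    L = p_up[:, :, None] * ker
    return M, K, L
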