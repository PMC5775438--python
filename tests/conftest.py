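"""Shared fixtures and the dense absorbing-chain oracle.

The oracle builds the full ``(N+1)k x (N+1)k`` one-step transition matrix
of the joint chain and computes fixation probabilities and epsilon-weighted
times by dense linear algebra on the fundamental matrix — a route entirely
independent of the block-tridiagonal solvers it is used to check.
"""

from __future__ import annotations

import numpy as np
import pytest

from coculture.core_model import CoupledModel, block_arrays


def dense_transition_matrix(model: CoupledModel) -> np.ndarray:
    """Full one-step matrix over states ordered (i major, culture minor)."""
    M, K, L = block_arrays(model)
    N, k = model.N, model.k
    P = np.zeros(((N + 1) * k, (N + 1) * k))
    for i in range(N + 1):
        rows = slice(i * k, (i + 1) * k)
        P[rows, rows] = K[i]
        if i > 0:
            P[rows, (i - 1) * k : i * k] = M[i]
        if i < N:
            P[rows, (i + 1) * k : (i + 2) * k] = L[i]
    return P


def dense_absorption(model: CoupledModel):
    """Fixation probabilities and times from the fundamental matrix.

    Levels ``i = 0`` and ``i = N`` are treated as the two absorbing classes
    (culture keeps moving inside them but the biological outcome is
    decided).  Returns ``(epsilon, tau)`` arrays of shape ``(N+1, k)`` with
    times in replacement-event steps.
    """
    N, k = model.N, model.k
    P = dense_transition_matrix(model)
    transient = np.arange(k, N * k)          # levels 1 .. N-1
    absorbing = np.concatenate([np.arange(k), np.arange(N * k, (N + 1) * k)])
    Q = P[np.ix_(transient, transient)]
    R = P[np.ix_(transient, absorbing)]
    fund = np.linalg.inv(np.eye(len(transient)) - Q)
    hit_fixed = R[:, k:] @ np.ones(k)        # one-step probability into level N
    eps_t = fund @ hit_fixed
    tau_t = fund @ eps_t
    epsilon = np.zeros((N + 1, k))
    epsilon[1:N] = eps_t.reshape(N - 1, k)
    epsilon[N] = 1.0
    tau = np.zeros((N + 1, k))
    tau[1:N] = tau_t.reshape(N - 1, k)
    return epsilon, tau


@pytest.fixture
def dense_oracle():
    return dense_absorption
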