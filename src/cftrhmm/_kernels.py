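"""Compiled inner loops: Markov-chain sampling and scaled forward-backward.

These are the only two O(n) sequential recursions in the package; both are
numba-jitted so that million-sample chains and repeated EM E-steps stay
cheap.  Everything else is vectorized numpy.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def sample_chain(cum_rows: np.ndarray, cum_init: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Sample a state-index path from cumulative transition rows.

    ``cum_rows[i]`` is the cumulative sum of transition row i (last entry
    exactly 1), ``cum_init`` the cumulative initial distribution, ``u`` a
    vector of n iid Uniform(0,1) draws.
    """
    n = u.shape[0]
    S = cum_init.shape[0]
    s = np.empty(n, dtype=np.int64)
    j = 0
    while j < S - 1 and u[0] >= cum_init[j]:
        j += 1
    s[0] = j
    for k in range(1, n):
        row = cum_rows[s[k - 1]]
        j = 0
        while j < S - 1 and u[k] >= row[j]:
            j += 1
        s[k] = j
    return s


@njit(cache=False)
def forward_backward_core(B: np.ndarray, Q: np.ndarray, init: np.ndarray):
    """Scaled forward-backward on a chain with per-sample likelihoods B.

    B is the n x S matrix of (row-rescaled) emission likelihoods.  Returns
    the posterior marginals gamma (n x S), pairwise posteriors xi
    ((n-1) x S x S), and the per-step normalizers c (n,), whose log-sum is
    the log-likelihood up to the row rescaling of B.
    """
    n, S = B.shape
    alpha = np.empty((n, S))
    c = np.empty(n)
    tot = 0.0
    for j in range(S):
        alpha[0, j] = init[j] * B[0, j]
        tot += alpha[0, j]
    c[0] = tot
    for j in range(S):
        alpha[0, j] /= tot
    for k in range(1, n):
        tot = 0.0
        for j in range(S):
            acc = 0.0
            for i in range(S):
                acc += alpha[k - 1, i] * Q[i, j]
            acc *= B[k, j]
            alpha[k, j] = acc
            tot += acc
        c[k] = tot
        for j in range(S):
            alpha[k, j] /= tot

    beta = np.empty((n, S))
    for j in range(S):
        beta[n - 1, j] = 1.0
    bb = np.empty(S)
    for k in range(n - 2, -1, -1):
        for j in range(S):
            bb[j] = B[k + 1, j] * beta[k + 1, j]
        ck1 = c[k + 1]
        for i in range(S):
            acc = 0.0
            for j in range(S):
                acc += Q[i, j] * bb[j]
            beta[k, i] = acc / ck1

    gamma = alpha * beta
    xi = np.empty((n - 1, S, S))
    for k in range(n - 1):
        ck1 = c[k + 1]
        for j in range(S):
            bb[j] = B[k + 1, j] * beta[k + 1, j] / ck1
        for i in range(S):
            ai = alpha[k, i]
            for j in range(S):
                xi[k, i, j] = ai * Q[i, j] * bb[j]
    return gamma, xi, c
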