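"""Independent oracles used by the tests.

Everything here deliberately avoids the package's inference code paths:
posteriors come from exhaustive enumeration over all state sequences, the
matrix exponential from a truncated Taylor series, and the stationary
distribution from brute-force power iteration.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def enumerate_posterior(
    B: np.ndarray, Q: np.ndarray, init: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Exact marginals, pairwise posteriors, and log p(y) by full enumeration.

    ``B[k, i]`` is the (unnormalized) likelihood of sample k under state i.
    Cost is S^n; callers keep S^n small.
    """
    n, S = B.shape
    total = 0.0
    marg = np.zeros((n, S))
    xi = np.zeros((max(n - 1, 0), S, S))
    for path in itertools.product(range(S), repeat=n):
        p = init[path[0]] * B[0, path[0]]
        for k in range(1, n):
            p *= Q[path[k - 1], path[k]] * B[k, path[k]]
        total += p
        for k, s in enumerate(path):
            marg[k, s] += p
        for k in range(n - 1):
            xi[k, path[k], path[k + 1]] += p
    return marg / total, xi / total, math.log(total)


def gaussian_likelihoods(y: np.ndarray, levels: np.ndarray, sigma2: float) -> np.ndarray:
    """N(y_k; level_i, sigma2) for each sample/state, no rescaling."""
    return np.exp(-((y[:, None] - levels[None, :]) ** 2) / (2 * sigma2)) / np.sqrt(
        2 * np.pi * sigma2
    )


def taylor_expm(M: np.ndarray, terms: int = 60) -> np.ndarray:
    """Truncated-series matrix exponential sum_k M^k / k!."""
    out = np.eye(M.shape[0])
    term = np.eye(M.shape[0])
    for k in range(1, terms):
        term = term @ M / k
        out = out + term
    return out


def power_iteration_stationary(Q: np.ndarray, iters: int = 10_000) -> np.ndarray:
    """Row of Q^iters starting from uniform: brute-force stationary vector."""
    p = np.full(Q.shape[0], 1.0 / Q.shape[0])
    for _ in range(iters):
        p = p @ Q
    return p / p.sum()


def count_transition_ratios(labels: list[str], states: tuple[str, ...]) -> np.ndarray:
    """Empirical first-order transition probabilities of a label sequence."""
    S = len(states)
    counts = np.zeros((S, S))
    for a, b in zip(labels, labels[1:]):
        counts[states.index(a), states.index(b)] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return counts / totals
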