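"""Exact posterior inference on the gating chain by sum-product message passing.

The model is an aggregated hidden Markov chain: several microstates share a
conductance class and therefore share the same Gaussian observation density
N(A m(s), sigma^2).  On a chain factor graph, sum-product message passing
reduces to the forward-backward algorithm, and the marginals it returns are
exact.  Messages are renormalized at every step (scaled forward-backward);
the accumulated log-normalizers give the data log-likelihood for free, and
no underflow occurs even for million-sample traces.

Emission log-densities are computed once per conductance class per sample
and re-rescaled per sample before the recursion, so a sample far from both
current levels cannot underflow both classes to zero.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from . import _kernels
from .kinetics import KineticScheme, StateDistribution, TransitionMatrix
from .simulator import EmissionModel, Trace

__all__ = [
    "PosteriorMatrix",
    "PairwisePosterior",
    "DegenerateLikelihoodError",
    "forward_backward",
    "log_likelihood",
]


class DegenerateLikelihoodError(ValueError):
    """Raised when the observation model assigns zero likelihood to the data."""


@dataclasses.dataclass(frozen=True)
class PosteriorMatrix:
    """Per-sample posterior marginals p(s_k | y) and the data log-likelihood."""

    marginals: np.ndarray
    log_likelihood: float
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        g = np.asarray(self.marginals, dtype=float)
        object.__setattr__(self, "marginals", g)
        if g.ndim != 2 or g.shape[1] != len(self.states):
            raise ValueError("marginals must be n x n_states")
        if not math.isfinite(self.log_likelihood):
            raise DegenerateLikelihoodError(
                f"non-finite log-likelihood ({self.log_likelihood})"
            )

    def map_indices(self) -> np.ndarray:
        return self.marginals.argmax(axis=1)

    def confidence(self) -> np.ndarray:
        """Max posterior probability per sample."""
        return self.marginals.max(axis=1)


@dataclasses.dataclass(frozen=True)
class PairwisePosterior:
    """Pairwise transition posteriors xi[k, i, j] = p(s_k=i, s_{k+1}=j | y)."""

    xi: np.ndarray
    states: tuple[str, ...]


def _emission_likelihoods(
    y: np.ndarray, em: EmissionModel, m: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample state likelihoods, rescaled so each row has max 1.

    Returns (B, row_log_max): B[k, i] = exp(logpdf(y_k | state i) - row max)
    and the subtracted per-row log maxima, which re-enter the likelihood.
    States sharing a conductance class share a density, computed once per
    class per sample.
    """
    sigma2 = em.noise_variance
    levels = em.levels()  # index by conductance class
    if np.any(np.isnan(y)):
        raise ValueError("trace contains NaN samples")
    if sigma2 <= 0:
        # Noise-free limit: the likelihood is an indicator on the exact level.
        match = np.isclose(y[:, None], levels[None, :], rtol=0.0, atol=1e-12)
        if not np.all(match.any(axis=1)):
            raise DegenerateLikelihoodError(
                "sigma^2 = 0 but some samples lie off the two current levels"
            )
        B = match[:, m].astype(float)
        return B, np.zeros(y.size)
    # log N(y; level, sigma2) per conductance class, then expand to states
    log_class = -0.5 * np.log(2 * np.pi * sigma2) - (y[:, None] - levels[None, :]) ** 2 / (
        2 * sigma2
    )
    logB = log_class[:, m]
    row_max = logB.max(axis=1)
    B = np.exp(logB - row_max[:, None])
    return B, row_max


def forward_backward(
    y: Trace,
    Q: TransitionMatrix,
    em: EmissionModel,
    init: StateDistribution,
    scheme: KineticScheme,
) -> tuple[PosteriorMatrix, PairwisePosterior]:
    """Exact chain marginals and pairwise posteriors under the Gaussian HMM.

    Parameters
    ----------
    y
        Observed current trace.
    Q
        Discrete-time transition matrix at the trace's sampling interval.
    em
        Gaussian emission model (amplitude, noise variance).
    init
        Distribution of the first hidden state.
    scheme
        Kinetic scheme providing the state -> conductance-class map.

    Returns
    -------
    posterior, pairwise
        Marginals p(s_k | y) with the data log-likelihood, and the
        (n-1) x S x S array of transition posteriors used by the EM E-step.
    """
    if scheme.state_names != Q.states or init.states != Q.states:
        raise ValueError("scheme, Q, and init must share the same state labels")
    obs = np.asarray(y.samples, dtype=float)
    m = scheme.conductance_vector()
    B, row_log_max = _emission_likelihoods(obs, em, m)
    gamma, xi, c = _kernels.forward_backward_core(
        np.ascontiguousarray(B),
        np.ascontiguousarray(Q.values),
        np.ascontiguousarray(init.probs),
    )
    if not np.all(c > 0) or not np.all(np.isfinite(c)):
        raise DegenerateLikelihoodError(
            "zero-probability observation under the model (check sigma^2 and Q)"
        )
    ll = float(np.log(c).sum() + row_log_max.sum())
    post = PosteriorMatrix(gamma, log_likelihood=ll, states=Q.states)
    return post, PairwisePosterior(xi, states=Q.states)


def log_likelihood(
    y: Trace,
    Q: TransitionMatrix,
    em: EmissionModel,
    init: StateDistribution,
    scheme: KineticScheme,
) -> float:
    """Log of p(y) under the hidden Markov model (same inputs as forward_backward)."""
    post, _ = forward_backward(y, Q, em, init, scheme)
    return post.log_likelihood
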