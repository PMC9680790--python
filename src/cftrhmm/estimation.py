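"""Factor-graph EM: joint estimation of Q, sigma^2, and optionally A.

The transition matrix, noise variance, and (for real recordings) the
current amplitude are unknown a priori.  They are estimated by
expectation-maximization in which the E-step expectations come from
sum-product message passing on the chain factor graph
(:func:`cftrhmm.inference.forward_backward`) and the M-step has the usual
closed forms:

    Q_ij      <-  sum_k xi[k, i, j] / sum_k gamma[k, i]   (then masked
                  to the scheme topology + self-loops and row-renormalized)
    sigma^2   <-  sum_k sum_i gamma[k, i] (y_k - A m(i))^2 / n
    A         <-  sum_k sum_{i open} gamma[k, i] y_k
                  / sum_k sum_{i open} gamma[k, i]          (optional)

Q is estimated directly in discrete time with the scheme's allowed-edge set
(plus self-loops) as a hard constraint.  exp(R dt) is technically dense,
but its off-topology mass is O(dt^2); the hard constraint is what makes
the five electrically identical closed states identifiable, and it is the
central modeling decision of this module.

The iteration count is fixed (default 400) rather than stopping on a
tolerance; an optional early-stop tolerance is available but off by
default.  The initial state distribution used for inference is the
stationary distribution of the current Q estimate, matching a channel
recorded in steady state.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .inference import PosteriorMatrix, forward_backward
from .kinetics import KineticScheme, StateDistribution, TransitionMatrix, stationary_distribution
from .simulator import EmissionModel, Trace

__all__ = ["EMConfig", "EMResult", "InitializationError", "initialize", "em_fit"]

logger = logging.getLogger(__name__)


class InitializationError(ValueError):
    """Raised when a trace cannot seed the EM (e.g. no openings detected)."""


@dataclasses.dataclass(frozen=True)
class EMConfig:
    """EM settings.

    Parameters
    ----------
    n_iterations
        Fixed number of EM iterations (default 400).
    estimate_amplitude
        Update A in the M-step.  Off by default (simulation benchmarks fix
        A at its true value); turn on for real recordings.
    estimate_sigma2
        Update sigma^2 in the M-step (default True).
    amplitude, sigma2
        Optional overrides for the data-driven initial values; when the
        corresponding ``estimate_*`` flag is off, the value stays fixed.
    seed
        Seed for the random jitter applied to the initial Q.
    min_sigma2
        Floor on the variance estimate; prevents likelihood blow-up on
        noise-free traces.
    early_stop_tol
        Optional relative log-likelihood tolerance for early stopping;
        None (default) runs all iterations.
    """

    n_iterations: int = 400
    estimate_amplitude: bool = False
    estimate_sigma2: bool = True
    amplitude: float | None = None
    sigma2: float | None = None
    seed: int = 0
    min_sigma2: float = 1e-8
    early_stop_tol: float | None = None

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not self.min_sigma2 > 0:
            raise ValueError("min_sigma2 must be positive")


@dataclasses.dataclass(frozen=True)
class EMResult:
    """Fitted parameters, log-likelihood trajectory, and final posterior."""

    Q_hat: TransitionMatrix
    sigma2_hat: float
    amplitude_hat: float
    loglik_trajectory: np.ndarray
    final_posterior: PosteriorMatrix

    @property
    def emission(self) -> EmissionModel:
        return EmissionModel(self.amplitude_hat, self.sigma2_hat)


def _two_level_split(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mid = 0.5 * (y.min() + y.max())
    lower = y[y <= mid]
    upper = y[y > mid]
    return lower, upper


def initialize(
    y: Trace, scheme: KineticScheme, config: EMConfig
) -> tuple[TransitionMatrix, EmissionModel, StateDistribution]:
    """Data-driven EM starting point: two-level amplitude/variance, jittered Q.

    The amplitude guess is the gap between the means of the samples above
    and below the midpoint of (min, max); the variance guess is the pooled
    within-cluster variance.  Q0 puts probability 0.05 (1 + u),
    u ~ Uniform(-0.5, 0.5), on each allowed off-diagonal transition and the
    remainder on the self-loop.

    Raises
    ------
    InitializationError
        If the two levels are not separated beyond the within-level noise
        ("no openings detected").
    """
    obs = np.asarray(y.samples, dtype=float)
    if obs.size < 2:
        raise InitializationError("need at least 2 samples to initialize EM")
    lower, upper = _two_level_split(obs)
    if lower.size == 0 or upper.size == 0:
        raise InitializationError("no openings detected: trace has a single level")
    A0 = float(upper.mean() - lower.mean())
    pooled = (
        float(((lower - lower.mean()) ** 2).sum() + ((upper - upper.mean()) ** 2).sum())
        / obs.size
    )
    sigma0 = max(pooled, config.min_sigma2)
    if A0 <= 3.0 * np.sqrt(sigma0):
        raise InitializationError(
            "no openings detected: level separation "
            f"{A0:.3g} is within the noise ({np.sqrt(sigma0):.3g} rms)"
        )
    if config.amplitude is not None:
        A0 = config.amplitude
    if config.sigma2 is not None:
        sigma0 = max(config.sigma2, config.min_sigma2)

    rng = np.random.default_rng(config.seed)
    mask = scheme.adjacency()
    n = scheme.n_states
    Q0 = np.zeros((n, n))
    u = rng.uniform(-0.5, 0.5, size=(n, n))
    Q0[mask] = 0.05 * (1.0 + u[mask])
    np.fill_diagonal(Q0, 0.0)
    np.fill_diagonal(Q0, 1.0 - Q0.sum(axis=1))
    Q0 /= Q0.sum(axis=1, keepdims=True)
    Qmat = TransitionMatrix(Q0, dt=y.dt, states=scheme.state_names)
    return Qmat, EmissionModel(A0, sigma0), stationary_distribution(Qmat)


def em_fit(
    y: Trace,
    scheme: KineticScheme,
    config: EMConfig | None = None,
    Q0: TransitionMatrix | None = None,
) -> EMResult:
    """Fit Q, sigma^2 (and optionally A) to a trace by factor-graph EM.

    Runs exactly ``config.n_iterations`` iterations (unless the optional
    early-stop tolerance fires).  Each iteration recomputes the inference
    initial distribution as the stationary distribution of the current Q,
    runs a sum-product E-step, and applies the closed-form M-step with the
    scheme topology as a hard constraint, so off-topology entries of Q_hat
    are exactly zero after every iteration.  ``Q0`` overrides the jittered
    starting transition matrix (useful for warm starts).
    """
    if config is None:
        config = EMConfig()
    Q, em, init = initialize(y, scheme, config)
    if Q0 is not None:
        if Q0.states != scheme.state_names:
            raise ValueError("Q0 state labels do not match the scheme")
        Q = Q0
    obs = np.asarray(y.samples, dtype=float)
    n = obs.size
    m = scheme.conductance_vector()
    open_cols = m == 1
    mask_full = scheme.adjacency() | np.eye(scheme.n_states, dtype=bool)

    logliks = []
    Qv = Q.values.copy()
    A = em.amplitude
    sigma2 = em.noise_variance
    post = None
    for it in range(config.n_iterations):
        Qmat = TransitionMatrix(Qv, dt=y.dt, states=scheme.state_names)
        init = stationary_distribution(Qmat)
        post, pair = forward_backward(y, Qmat, EmissionModel(A, sigma2), init, scheme)
        logliks.append(post.log_likelihood)
        gamma = post.marginals

        # M-step: transition matrix
        xi_sum = pair.xi.sum(axis=0)
        num = np.where(mask_full, xi_sum, 0.0)
        denom = num.sum(axis=1)
        new_Q = Qv.copy()
        ok = denom > 0
        new_Q[ok] = num[ok] / denom[ok, None]
        if not np.all(ok):
            dead = [scheme.state_names[i] for i in np.flatnonzero(~ok)]
            logger.warning(
                "EM iteration %d: zero expected occupancy for %s; keeping previous rows",
                it,
                dead,
            )
        Qv = new_Q

        # M-step: emission parameters
        if config.estimate_amplitude:
            w_open = gamma[:, open_cols].sum(axis=1)
            tot = w_open.sum()
            if tot > 0:
                A = float((w_open * obs).sum() / tot)
        if config.estimate_sigma2:
            levels = A * m.astype(float)
            resid2 = (obs[:, None] - levels[None, :]) ** 2
            sigma2 = max(float((gamma * resid2).sum() / n), config.min_sigma2)

        if config.early_stop_tol is not None and it > 0:
            prev, cur = logliks[-2], logliks[-1]
            if abs(cur - prev) <= config.early_stop_tol * abs(prev):
                logger.info("EM early stop at iteration %d", it)
                break

    Qmat = TransitionMatrix(Qv, dt=y.dt, states=scheme.state_names)
    final_post, _ = forward_backward(
        y, Qmat, EmissionModel(A, sigma2), stationary_distribution(Qmat), scheme
    )
    return EMResult(
        Q_hat=Qmat,
        sigma2_hat=sigma2,
        amplitude_hat=A,
        loglik_trajectory=np.asarray(logliks),
        final_posterior=final_post,
    )
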