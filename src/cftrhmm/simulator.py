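"""Monte Carlo simulation of gating state sequences and noisy current traces.

The hidden state sequence s = [s_1 ... s_n] is a discrete-time Markov chain
with transition matrix Q = exp(R dt).  The patch clamp observes

    y_k = A m(s_k) + n_k,

where m maps each microstate to its conductance class (0 closed, 1 open),
A is the single-channel current amplitude, and n_k is iid Gaussian noise
with zero mean and variance sigma^2.

A single integer seed drives both the chain and the noise through two
independent sub-streams, so the same state sequence is produced whether or
not noise is drawn.
"""

from __future__ import annotations

import dataclasses
from functools import cached_property

import numpy as np

from . import _kernels
from .kinetics import (
    KineticScheme,
    StateDistribution,
    TransitionMatrix,
    discretize,
    rate_matrix,
    stationary_distribution,
)

__all__ = [
    "EmissionModel",
    "StateSequence",
    "Trace",
    "sample_states",
    "emit_current",
    "simulate_trace",
]


@dataclasses.dataclass(frozen=True)
class EmissionModel:
    """Gaussian emission parameters: open-channel amplitude and noise variance."""

    amplitude: float
    noise_variance: float

    def __post_init__(self) -> None:
        if self.noise_variance < 0:
            raise ValueError("noise variance must be nonnegative")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive after polarity normalization")

    def levels(self) -> np.ndarray:
        """Mean current per conductance class: [closed, open]."""
        return np.array([0.0, self.amplitude])


@dataclasses.dataclass(frozen=True)
class StateSequence:
    """A sampled path of hidden microstates at interval dt."""

    indices: np.ndarray
    states: tuple[str, ...]
    dt: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        object.__setattr__(self, "indices", idx)
        if idx.ndim != 1 or idx.size < 1:
            raise ValueError("state sequence must be a nonempty 1-D index array")
        if idx.min() < 0 or idx.max() >= len(self.states):
            raise ValueError("state index out of range")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return self.indices.size

    @cached_property
    def labels(self) -> list[str]:
        return [self.states[i] for i in self.indices]

    def conductance(self, scheme: KineticScheme) -> np.ndarray:
        return scheme.conductance_vector()[self.indices]


@dataclasses.dataclass(frozen=True)
class Trace:
    """Observed current samples with sampling interval and emission model.

    ``emission`` is known exactly for simulated traces and None for real
    recordings until estimated.
    """

    samples: np.ndarray
    dt: float
    emission: EmissionModel | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", y)
        if y.ndim != 1 or y.size < 1:
            raise ValueError("trace must be a nonempty 1-D sample vector")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return self.samples.size

    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt


def _rng(seed: int | np.random.SeedSequence | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_states(
    Q: TransitionMatrix,
    n: int,
    init: StateDistribution,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> StateSequence:
    """Draw a length-n hidden-state path: s_1 ~ init, s_k | s_{k-1} ~ Q row."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if init.states != Q.states:
        raise ValueError("initial distribution and Q use different state labels")
    rng = _rng(seed)
    cum_rows = np.cumsum(Q.values, axis=1)
    cum_rows[:, -1] = 1.0
    cum_init = np.cumsum(init.probs)
    cum_init[-1] = 1.0
    u = rng.random(n)
    idx = _kernels.sample_chain(cum_rows, cum_init, u)
    return StateSequence(idx, states=Q.states, dt=Q.dt)


def emit_current(
    s: StateSequence,
    em: EmissionModel,
    seed: int | np.random.SeedSequence | np.random.Generator,
    scheme: KineticScheme | None = None,
    conductance: np.ndarray | None = None,
) -> Trace:
    """Emit the noisy current y_k = A m(s_k) + N(0, sigma^2) for a state path.

    The conductance classes are taken from ``scheme`` (matched by state
    label) or given directly via ``conductance`` (one 0/1 per scheme state).
    """
    if conductance is None:
        if scheme is None:
            raise ValueError("provide either a scheme or a conductance vector")
        if scheme.state_names != s.states:
            raise ValueError("scheme and state sequence use different state labels")
        conductance = scheme.conductance_vector()
    m = np.asarray(conductance)[s.indices]
    y = em.amplitude * m.astype(float)
    if em.noise_variance > 0:
        rng = _rng(seed)
        y = y + rng.normal(0.0, np.sqrt(em.noise_variance), size=y.size)
    return Trace(y, dt=s.dt, emission=em)


def simulate_trace(
    scheme: KineticScheme,
    atp: float,
    dt: float,
    n: int,
    em: EmissionModel,
    seed: int | np.random.SeedSequence,
    init: StateDistribution | None = None,
) -> tuple[StateSequence, Trace]:
    """Simulate a ground-truth state path and its noisy current trace.

    Builds R at the given ATP concentration, discretizes to Q, starts the
    chain from its stationary distribution (a channel observed in steady
    state) unless ``init`` overrides it, and adds Gaussian noise.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    chain_ss, noise_ss = ss.spawn(2)
    Q = discretize(rate_matrix(scheme, atp), dt)
    if init is None:
        init = stationary_distribution(Q)
    s = sample_states(Q, n, init, np.random.default_rng(chain_ss))
    y = emit_current(s, em, np.random.default_rng(noise_ss), scheme=scheme)
    return s, y
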