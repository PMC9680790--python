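"""Seven-state CFTR gating scheme and its continuous/discrete-time matrices.

The CFTR chloride channel is modeled as a continuous-time Markov chain over
seven kinetic microstates: five electrically closed states (C1a, C1b, C2,
C3, C4) and two open states (O1, O2).  The gating cycle contains two
irreversible steps — ATP hydrolysis (O1 -> O2) and ADP release (C4 -> C1a)
— so the reverse edges O2 -> O1 and C1a -> C4 do not exist.  ATP binding
(C1a -> C1b) is the single concentration-dependent step: its effective rate
is the second-order rate constant times the molar ATP concentration.

The master equation for the row vector of state probabilities P is

    dP/dt = P R

with R the generator (rate) matrix: off-diagonal R[i, j] is the transition
rate from state i to state j and each diagonal entry makes its row sum to
zero.  Sampling at interval ``dt`` turns the chain into a discrete-time
Markov chain with transition probability matrix

    Q = exp(R dt).

This module provides the default wild-type scheme with its published rate
constants, a plain-text scheme file format for user-supplied variants
(e.g. mutant rate sets), and the matrix operations used by the simulator
and inference code.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.linalg import expm
from scipy.sparse.csgraph import connected_components

__all__ = [
    "STATE_ORDER",
    "KineticScheme",
    "RateMatrix",
    "TransitionMatrix",
    "StateDistribution",
    "SchemeError",
    "ReducibleChainError",
    "build_cftr_scheme",
    "rate_matrix",
    "discretize",
    "stationary_distribution",
    "embedded_jump_chain",
    "evolve",
    "load_scheme",
    "dump_scheme",
]

#: Canonical state ordering used for every matrix in the package.
STATE_ORDER = ("C1a", "C1b", "C2", "O1", "O2", "C3", "C4")

_DEFAULT_CONDUCTANCE = {
    "C1a": 0, "C1b": 0, "C2": 0, "O1": 1, "O2": 1, "C3": 0, "C4": 0,
}

# Rate constants of the wild-type (high open-probability) model.  Units are
# s^-1, except the ATP-binding edge C1a -> C1b which is (M s)^-1.
_DEFAULT_RATES = {
    ("C1a", "C1b"): 9.0e3,
    ("C1b", "C1a"): 5.0,
    ("C1b", "C2"): 7.7,
    ("C2", "C1b"): 5.8,
    ("C2", "O1"): 4.9,
    ("O1", "C2"): 10.0,
    ("O1", "O2"): 7.1,
    ("O2", "C3"): 3.0,
    ("C3", "O2"): 7.0,
    ("C3", "C4"): 6.0,
    ("C4", "C3"): 12.8,
    ("C4", "C1a"): 1.7,
}

_DEFAULT_ATP_EDGES = frozenset({("C1a", "C1b")})


class SchemeError(ValueError):
    """Raised for an inconsistent kinetic scheme or scheme file."""


class ReducibleChainError(ValueError):
    """Raised when a chain has no unique stationary distribution."""


@dataclasses.dataclass(frozen=True)
class KineticScheme:
    """A kinetic scheme: states, conductance classes, edges, and rates.

    Parameters
    ----------
    state_names
        Ordered state labels; this order indexes every matrix built from
        the scheme.
    conductance_map
        State label -> conductance class (0 = closed, 1 = open).
    rate_params
        Directed edge ``(origin, destination)`` -> rate constant.  Units
        are s^-1, or (M s)^-1 for ATP-dependent edges.  The key set *is*
        the allowed-transition topology.
    atp_dependent_edges
        Edges whose effective rate is ``rate * [ATP]``.
    """

    state_names: tuple[str, ...]
    conductance_map: Mapping[str, int]
    rate_params: Mapping[tuple[str, str], float]
    atp_dependent_edges: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        names = self.state_names
        if len(set(names)) != len(names) or not names:
            raise SchemeError("state names must be unique and nonempty")
        missing = set(names) - set(self.conductance_map)
        if missing:
            raise SchemeError(f"states without conductance class: {sorted(missing)}")
        bad = {s: v for s, v in self.conductance_map.items() if v not in (0, 1)}
        if bad:
            raise SchemeError(f"conductance classes must be 0 or 1, got {bad}")
        for (i, j), rate in self.rate_params.items():
            if i not in names or j not in names:
                raise SchemeError(f"edge ({i}, {j}) references unknown state")
            if i == j:
                raise SchemeError(f"self-edge ({i}, {i}) not allowed in a rate scheme")
            if not rate > 0:
                raise SchemeError(f"rate for edge ({i}, {j}) must be > 0, got {rate}")
        extra = set(self.atp_dependent_edges) - set(self.rate_params)
        if extra:
            raise SchemeError(f"ATP-dependent edges not in the edge set: {sorted(extra)}")

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.rate_params)

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def index(self, label: str) -> int:
        return self.state_names.index(label)

    def conductance_vector(self) -> np.ndarray:
        """Conductance class per state, in scheme order."""
        return np.array([self.conductance_map[s] for s in self.state_names], dtype=np.int64)

    def open_states(self) -> tuple[str, ...]:
        return tuple(s for s in self.state_names if self.conductance_map[s] == 1)

    def adjacency(self) -> np.ndarray:
        """Boolean matrix: True where a directed edge exists."""
        n = self.n_states
        mask = np.zeros((n, n), dtype=bool)
        for i, j in self.rate_params:
            mask[self.index(i), self.index(j)] = True
        return mask


@dataclasses.dataclass(frozen=True)
class RateMatrix:
    """Continuous-time generator matrix R (s^-1) at a fixed [ATP]."""

    values: np.ndarray
    atp_concentration: float
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.states):
            raise ValueError("rate matrix must be square and match the state labels")
        off = v - np.diag(np.diag(v))
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be nonnegative")
        if np.max(np.abs(v.sum(axis=1))) > 1e-9 * max(1.0, np.max(np.abs(v))):
            raise ValueError("each row of a generator matrix must sum to zero")


@dataclasses.dataclass(frozen=True)
class TransitionMatrix:
    """Discrete-time stochastic matrix Q with its sampling interval."""

    values: np.ndarray
    dt: float
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.states):
            raise ValueError("transition matrix must be square and match the state labels")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if np.max(np.abs(v.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("each row of a transition matrix must sum to 1")


@dataclasses.dataclass(frozen=True)
class StateDistribution:
    """Probability row vector over scheme states."""

    probs: np.ndarray
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.ndim != 1 or p.shape[0] != len(self.states):
            raise ValueError("distribution length must match the state labels")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be nonnegative and sum to 1")

    @classmethod
    def point_mass(cls, label: str, states: tuple[str, ...]) -> "StateDistribution":
        p = np.zeros(len(states))
        p[states.index(label)] = 1.0
        return cls(p, states)


def build_cftr_scheme() -> KineticScheme:
    """Return the default seven-state wild-type CFTR scheme.

    Twelve directed edges form the gating cycle; C1a -> C1b is the single
    ATP-dependent (second-order) step, and neither O2 -> O1 nor C1a -> C4
    exists (hydrolysis and ADP release are irreversible).
    """
    return KineticScheme(
        state_names=STATE_ORDER,
        conductance_map=dict(_DEFAULT_CONDUCTANCE),
        rate_params=dict(_DEFAULT_RATES),
        atp_dependent_edges=_DEFAULT_ATP_EDGES,
    )


def rate_matrix(scheme: KineticScheme, atp: float) -> RateMatrix:
    """Build the generator matrix R for a scheme at molar ATP concentration.

    Off-diagonal entry (i, j) is the edge's rate constant, multiplied by
    ``atp`` on ATP-dependent edges; diagonals make rows sum to zero.
    """
    if not atp > 0:
        raise ValueError(f"ATP concentration must be positive (molar), got {atp}")
    n = scheme.n_states
    R = np.zeros((n, n))
    for (i, j), rate in scheme.rate_params.items():
        eff = rate * atp if (i, j) in scheme.atp_dependent_edges else rate
        R[scheme.index(i), scheme.index(j)] = eff
    np.fill_diagonal(R, 0.0)
    np.fill_diagonal(R, -R.sum(axis=1))
    return RateMatrix(R, atp_concentration=atp, states=scheme.state_names)


def discretize(R: RateMatrix, dt: float) -> TransitionMatrix:
    """Discretize a generator to the sampled-chain transition matrix.

    Q = exp(R dt), computed with scipy's scaling-and-squaring matrix
    exponential.  Entries that round to tiny negatives are clipped to 0.
    """
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    Q = expm(R.values * dt)
    Q[Q < 0] = 0.0
    return TransitionMatrix(Q, dt=dt, states=R.states)


def stationary_distribution(Q: TransitionMatrix) -> StateDistribution:
    """Stationary distribution pi of an irreducible chain: pi Q = pi.

    Solves the linear system (Q^T - I) pi = 0 with the normalization
    constraint replacing one equation.  Raises :class:`ReducibleChainError`
    if the positive-support graph of Q is not strongly connected, reporting
    the communicating classes.
    """
    V = Q.values
    n = V.shape[0]
    if n > 1:
        ncomp, labels = connected_components(V > 0, directed=True, connection="strong")
        if ncomp > 1:
            classes = [
                [Q.states[i] for i in range(n) if labels[i] == c] for c in range(ncomp)
            ]
            raise ReducibleChainError(
                f"chain is reducible; communicating classes: {classes}"
            )
    A = V.T - np.eye(n)
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    pi = np.linalg.solve(A, b)
    pi[pi < 0] = 0.0
    pi /= pi.sum()
    return StateDistribution(pi, states=Q.states)


def embedded_jump_chain(R: RateMatrix) -> TransitionMatrix:
    """Embedded jump chain of a generator: P[i, j] = R[i, j] / -R[i, i].

    Unlike the sampled chain exp(R dt) — which is dense because several
    transitions can occur between consecutive samples — the jump chain is
    supported exactly on the scheme edges, so every consecutive state pair
    of a sampled path is a genuine single transition.  The chain has no
    physical time base; ``dt`` is set to 1 jump by convention.
    """
    V = R.values
    exit_rates = -np.diag(V)
    if np.any(exit_rates <= 0):
        raise ValueError("every state needs a positive exit rate for a jump chain")
    P = V / exit_rates[:, None]
    np.fill_diagonal(P, 0.0)
    return TransitionMatrix(P, dt=1.0, states=R.states)


def evolve(P0: StateDistribution, R: RateMatrix, t: float) -> StateDistribution:
    """Propagate a state distribution for time t under the master equation.

    Returns P0 exp(R t); probability is conserved exactly (up to rounding)
    because rows of R sum to zero.
    """
    if t < 0:
        raise ValueError(f"time must be nonnegative, got {t}")
    if P0.states != R.states:
        raise ValueError("distribution and rate matrix use different state labels")
    p = P0.probs @ expm(R.values * t)
    p[p < 0] = 0.0
    p /= p.sum()
    return StateDistribution(p, states=P0.states)


# ---------------------------------------------------------------------------
# Plain-text scheme files
#
#   # comment
#   state <label> <conductance 0|1>
#   edge <origin> <destination> <rate> [atp]
#
# One `state` line per state (file order fixes the matrix order), one `edge`
# line per directed transition.  The `atp` flag marks a second-order
# ATP-binding step whose rate is multiplied by the molar concentration.
# ---------------------------------------------------------------------------

def load_scheme(path: str | Path) -> KineticScheme:
    """Parse a kinetic scheme from a plain-text scheme file."""
    names: list[str] = []
    cond: dict[str, int] = {}
    rates: dict[tuple[str, str], float] = {}
    atp_edges: set[tuple[str, str]] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        kind = tokens[0].lower()
        try:
            if kind == "state":
                label, c = tokens[1], int(tokens[2])
                names.append(label)
                cond[label] = c
            elif kind == "edge":
                i, j, rate = tokens[1], tokens[2], float(tokens[3])
                rates[(i, j)] = rate
                flags = [t.lower() for t in tokens[4:]]
                if "atp" in flags:
                    atp_edges.add((i, j))
                unknown = set(flags) - {"atp"}
                if unknown:
                    raise SchemeError(f"unknown edge flag(s) {sorted(unknown)}")
            else:
                raise SchemeError(f"unknown directive {kind!r}")
        except (IndexError, ValueError) as exc:
            if isinstance(exc, SchemeError):
                raise SchemeError(f"{path}:{lineno}: {exc}") from None
            raise SchemeError(f"{path}:{lineno}: malformed line {raw!r}") from exc
    try:
        return KineticScheme(tuple(names), cond, rates, frozenset(atp_edges))
    except SchemeError as exc:
        raise SchemeError(f"{path}: {exc}") from None


def dump_scheme(scheme: KineticScheme, path: str | Path) -> None:
    """Write a scheme to the plain-text scheme file format."""
    lines = [f"state {s} {scheme.conductance_map[s]}" for s in scheme.state_names]
    for (i, j), rate in scheme.rate_params.items():
        flag = " atp" if (i, j) in scheme.atp_dependent_edges else ""
        lines.append(f"edge {i} {j} {rate!r}{flag}")
    Path(path).write_text("\n".join(lines) + "\n")
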