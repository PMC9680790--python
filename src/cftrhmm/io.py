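"""CSV/JSON readers and writers for traces, parameters, events, and configs.

CSV is the interchange format (patch-clamp exports and spreadsheets both
speak it); parameter sets are JSON with state-labeled matrices so that the
matrix ordering is always checkable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import ClosingEvent
from .kinetics import TransitionMatrix
from .simulator import EmissionModel, StateSequence, Trace

__all__ = [
    "ConfigurationError",
    "TraceParseError",
    "RunConfig",
    "read_trace",
    "write_trace",
    "read_truth",
    "write_truth",
    "read_params",
    "write_params",
    "write_events",
    "write_posterior",
    "write_metrics",
]


class ConfigurationError(ValueError):
    pass


class TraceParseError(ValueError):
    pass


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as exc:
        # pandas names the offending line in its message
        raise TraceParseError(f"{path}: {exc}") from None


def _numeric(df: pd.DataFrame, col: str, path: str | Path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.index[vals.isna() & df[col].notna()]
    if len(bad):
        # +2: one for the header line, one for 0- vs 1-based numbering
        raise TraceParseError(
            f"{path}: non-numeric value in column {col!r} at line {bad[0] + 2}"
        )
    if vals.isna().any():
        raise TraceParseError(f"{path}: missing value in column {col!r}")
    return vals.to_numpy(dtype=float)


def _resolve_dt(
    df: pd.DataFrame, path: str | Path, rate: float | None, dt: float | None
) -> float:
    if dt is not None:
        return float(dt)
    if rate is not None:
        return 1.0 / float(rate)
    if "time_s" in df.columns:
        t = _numeric(df, "time_s", path)
        if t.size < 2:
            raise ConfigurationError(f"{path}: cannot infer dt from a single time sample")
        steps = np.diff(t)
        if np.max(np.abs(steps - steps[0])) > 1e-9 * max(1.0, abs(steps[0])):
            raise ConfigurationError(f"{path}: time column is not uniformly sampled")
        return float(steps[0])
    raise ConfigurationError(
        f"{path}: sampling interval unknown — provide a time_s column, --rate, or --dt"
    )


def read_trace(
    path: str | Path, rate: float | None = None, dt: float | None = None
) -> Trace:
    """Read a current trace CSV (column ``current``, optional ``time_s``)."""
    df = _read_csv(path)
    if "current" not in df.columns:
        raise TraceParseError(f"{path}: missing required column 'current'")
    y = _numeric(df, "current", path)
    return Trace(y, dt=_resolve_dt(df, path, rate, dt))


def write_trace(trace: Trace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.times(), "current": trace.samples}).to_csv(
        path, index=False
    )


def write_truth(seq: StateSequence, path: str | Path) -> None:
    times = np.arange(len(seq)) * seq.dt
    pd.DataFrame({"time_s": times, "state": seq.labels}).to_csv(path, index=False)


def read_truth(path: str | Path, states: tuple[str, ...]) -> StateSequence:
    df = _read_csv(path)
    for col in ("time_s", "state"):
        if col not in df.columns:
            raise TraceParseError(f"{path}: missing required column {col!r}")
    labels = df["state"].astype(str).tolist()
    unknown = sorted(set(labels) - set(states))
    if unknown:
        raise TraceParseError(f"{path}: unknown state labels {unknown}")
    t = _numeric(df, "time_s", path)
    dt = float(t[1] - t[0]) if t.size > 1 else 1.0
    idx = np.array([states.index(lab) for lab in labels], dtype=np.int64)
    return StateSequence(idx, states=states, dt=dt)


def write_params(
    Q: TransitionMatrix, em: EmissionModel, path: str | Path
) -> None:
    """Write fitted parameters as labeled JSON."""
    payload = {
        "states": list(Q.states),
        "dt_s": Q.dt,
        "Q": {
            origin: {dest: Q.values[i, j] for j, dest in enumerate(Q.states)}
            for i, origin in enumerate(Q.states)
        },
        "sigma2": em.noise_variance,
        "amplitude": em.amplitude,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_params(path: str | Path) -> tuple[TransitionMatrix, EmissionModel]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        payload = json.loads(path.read_text())
        states = tuple(payload["states"])
        V = np.array(
            [[payload["Q"][i][j] for j in states] for i in states], dtype=float
        )
        Q = TransitionMatrix(V, dt=float(payload["dt_s"]), states=states)
        em = EmissionModel(float(payload["amplitude"]), float(payload["sigma2"]))
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise ConfigurationError(f"{path}: malformed parameter file ({exc})") from None
    return Q, em


def write_events(events: list[ClosingEvent], dt: float, path: str | Path) -> None:
    rows = [
        {
            "start_s": e.closed_start * dt,
            "end_s": (e.closed_end + 1) * dt,
            "open_before_idx": e.open_before_idx,
            "open_after_idx": e.open_after_idx,
            "initial_state": e.initial_open_state,
            "final_state": e.final_open_state,
            "label": e.label,
            "confident": e.confident,
        }
        for e in events
    ]
    pd.DataFrame(
        rows,
        columns=[
            "start_s",
            "end_s",
            "open_before_idx",
            "open_after_idx",
            "initial_state",
            "final_state",
            "label",
            "confident",
        ],
    ).to_csv(path, index=False)


def write_posterior(marginals: np.ndarray, states: tuple[str, ...], dt: float, path) -> None:
    df = pd.DataFrame(marginals, columns=list(states))
    df.insert(0, "time_s", np.arange(marginals.shape[0]) * dt)
    df.to_csv(path, index=False)


def write_metrics(metrics, path: str | Path) -> None:
    payload = {
        "n_fa": metrics.n_fa,
        "n_md": metrics.n_md,
        "n_est_np": metrics.n_est_np,
        "n_gt_np": metrics.n_gt_np,
        "n_est_total": metrics.n_est_total,
        "n_gt_total": metrics.n_gt_total,
        "p_fa": metrics.p_fa if metrics.pfa_defined else None,
        "p_md": metrics.p_md if metrics.pmd_defined else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


_SWEEP_FIELDS = {
    "kind": str,
    "atp_min_molar": float,
    "atp_max_molar": float,
    "atp_points": int,
    "dt": float,
    "n": int,
    "sigma2": float,
    "amplitude": float,
    "em_iters": int,
    "thresholds": str,  # comma-separated
    "runs": int,
    "seed": int,
}


@dataclasses.dataclass
class RunConfig:
    """Validated sweep configuration; unknown keys are rejected on load."""

    kind: str = "prevalence"
    atp_min_molar: float = 0.05e-3
    atp_max_molar: float = 5e-3
    atp_points: int = 5
    dt: float = 0.01
    n: int = 1_000_000
    sigma2: float = 0.02
    amplitude: float = 1.0
    em_iters: int = 400
    thresholds: str = "0.0,0.8"
    runs: int = 10
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        values: dict[str, object] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line or line.startswith("["):
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}:{lineno}: expected key = value")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in _SWEEP_FIELDS:
                raise ConfigurationError(
                    f"{path}:{lineno}: unknown key {key!r}; "
                    f"allowed: {sorted(_SWEEP_FIELDS)}"
                )
            try:
                values[key] = _SWEEP_FIELDS[key](val)
            except ValueError:
                raise ConfigurationError(
                    f"{path}:{lineno}: cannot parse {val!r} for {key!r}"
                ) from None
        cfg = cls(**values)  # type: ignore[arg-type]
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.kind not in ("prevalence", "detection"):
            raise ConfigurationError(f"kind must be prevalence|detection, got {self.kind!r}")
        if not (0 < self.atp_min_molar <= self.atp_max_molar):
            raise ConfigurationError("need 0 < atp_min_molar <= atp_max_molar")
        for name in ("atp_points", "n", "em_iters", "runs"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not self.dt > 0:
            raise ConfigurationError("dt must be positive")
        if self.sigma2 < 0:
            raise ConfigurationError("sigma2 must be nonnegative")

    def atp_grid(self) -> np.ndarray:
        if self.atp_points == 1:
            return np.array([self.atp_min_molar])
        return np.logspace(
            np.log10(self.atp_min_molar), np.log10(self.atp_max_molar), self.atp_points
        )

    def threshold_list(self) -> tuple[float, ...]:
        return tuple(float(x) for x in self.thresholds.split(","))
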