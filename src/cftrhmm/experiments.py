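"""Scripted simulation studies: closing prevalence and detection error sweeps.

Two parameterized sweeps emit tidy one-row-per-(condition, run) tables:

* :func:`sweep_prevalence` — ground-truth statistics of closing rates and
  the nonpermissive/total ratio versus ATP concentration (no noise, no
  inference).  The ratio is expected near 1/12 and nearly independent of
  concentration.
* :func:`sweep_detection` — the full pipeline per run (simulate noisy
  trace -> EM fit -> posterior -> thresholded MAP -> closing extraction ->
  scoring), reporting P_FA and P_MD per confidence threshold.

All randomness derives from one seed; identical (seed, grid, runs) gives a
byte-identical table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .detection import extract_closings, map_threshold, score, NONPERMISSIVE
from .estimation import EMConfig, em_fit
from .kinetics import KineticScheme, discretize, rate_matrix, stationary_distribution
from .simulator import EmissionModel, sample_states, simulate_trace

__all__ = ["default_atp_grid", "sweep_prevalence", "sweep_detection", "plot_sweep"]


def default_atp_grid(n_points: int = 5) -> np.ndarray:
    """Logarithmic ATP grid from 0.05 to 5 mM (molar units)."""
    return np.logspace(np.log10(0.05e-3), np.log10(5e-3), n_points)


def _child_seeds(seed: int, count: int) -> np.ndarray:
    """Deterministic per-run integer seeds below 2**31."""
    return np.random.SeedSequence(seed).generate_state(count) % (2**31)


def sweep_prevalence(
    scheme: KineticScheme,
    atp_grid: np.ndarray | list[float],
    dt: float = 0.01,
    n: int = 1_000_000,
    runs: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Ground-truth closing prevalence per (ATP concentration, run).

    Simulates noise-free state paths from the stationary distribution and
    counts complete closings; reports total and nonpermissive closing rates
    (events per simulated second) and their ratio.
    """
    atp_grid = np.asarray(atp_grid, dtype=float)
    if atp_grid.size == 0:
        raise ValueError("atp_grid must be nonempty")
    seeds = _child_seeds(seed, atp_grid.size * runs).reshape(atp_grid.size, runs)
    rows = []
    for ai, atp in enumerate(atp_grid):
        Q = discretize(rate_matrix(scheme, atp), dt)
        init = stationary_distribution(Q)
        for run in range(runs):
            s = sample_states(Q, n, init, int(seeds[ai, run]))
            events = extract_closings(s, scheme)
            n_np = sum(1 for e in events if e.label == NONPERMISSIVE)
            duration = n * dt
            rows.append(
                {
                    "atp_molar": atp,
                    "run": run,
                    "seed": int(seeds[ai, run]),
                    "dt_s": dt,
                    "n_samples": n,
                    "n_closings": len(events),
                    "n_nonpermissive": n_np,
                    "total_rate_hz": len(events) / duration,
                    "nonpermissive_rate_hz": n_np / duration,
                    "np_fraction": n_np / len(events) if events else np.nan,
                }
            )
    return pd.DataFrame(rows)


def sweep_detection(
    scheme: KineticScheme,
    atp_grid: np.ndarray | list[float],
    dt: float = 0.01,
    n: int = 20_000,
    sigma2: float = 0.02,
    em_iters: int = 400,
    C_list: tuple[float, ...] = (0.0, 0.8),
    runs: int = 2,
    seed: int = 0,
    amplitude: float = 1.0,
    estimate_amplitude: bool = False,
) -> pd.DataFrame:
    """Detection error rates per (ATP concentration, confidence threshold, run).

    Benchmark mode: the amplitude is fixed at its true value by default
    (set ``estimate_amplitude`` to update it in the M-step too); Q and
    sigma^2 are always estimated from the trace by EM.  Closings are
    segmented from the ungated MAP sequence and gated through each event's
    confidence flag at every threshold in ``C_list``.
    """
    atp_grid = np.asarray(atp_grid, dtype=float)
    if atp_grid.size == 0:
        raise ValueError("atp_grid must be nonempty")
    sim_seeds = _child_seeds(seed, atp_grid.size * runs).reshape(atp_grid.size, runs)
    em_seeds = _child_seeds(seed + 1, atp_grid.size * runs).reshape(atp_grid.size, runs)
    em = EmissionModel(amplitude, sigma2)
    rows = []
    for ai, atp in enumerate(atp_grid):
        for run in range(runs):
            s_true, trace = simulate_trace(
                scheme, atp, dt, n, em, int(sim_seeds[ai, run])
            )
            config = EMConfig(
                n_iterations=em_iters,
                estimate_amplitude=estimate_amplitude,
                amplitude=None if estimate_amplitude else amplitude,
                seed=int(em_seeds[ai, run]),
            )
            result = em_fit(trace, scheme, config)
            est = map_threshold(result.final_posterior, 0.0)
            gt_events = extract_closings(s_true, scheme)
            for C in C_list:
                est_events = extract_closings(
                    est, scheme, confidence=est.confidence, threshold=C
                )
                metrics = score(gt_events, est_events, use_confident_only=True)
                rows.append(
                    {
                        "atp_molar": atp,
                        "C": C,
                        "run": run,
                        "sim_seed": int(sim_seeds[ai, run]),
                        "em_seed": int(em_seeds[ai, run]),
                        "dt_s": dt,
                        "n_samples": n,
                        "sigma2": sigma2,
                        "em_iters": em_iters,
                        "p_fa": metrics.p_fa,
                        "p_md": metrics.p_md,
                        "pfa_defined": metrics.pfa_defined,
                        "pmd_defined": metrics.pmd_defined,
                        "n_fa": metrics.n_fa,
                        "n_md": metrics.n_md,
                        "n_est_np": metrics.n_est_np,
                        "n_gt_np": metrics.n_gt_np,
                        "n_est_total": metrics.n_est_total,
                        "n_gt_total": metrics.n_gt_total,
                        "sigma2_hat": result.sigma2_hat,
                        "amplitude_hat": result.amplitude_hat,
                    }
                )
    return pd.DataFrame(rows)


def plot_sweep(table: pd.DataFrame, value: str, out_path: str | None = None):
    """Minimal dots-plus-mean-line plot of a sweep column versus [ATP]."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.semilogx(table["atp_molar"], table[value], "o", alpha=0.5, label="runs")
    means = table.groupby("atp_molar")[value].mean()
    ax.semilogx(means.index, means.values, "-", label="mean")
    ax.set_xlabel("[ATP] (M)")
    ax.set_ylabel(value)
    ax.legend()
    if out_path is not None:
        fig.savefig(out_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
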