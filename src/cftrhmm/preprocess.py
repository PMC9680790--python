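"""Raw-recording preparation: polarity/baseline normalization and decimation.

Patch-clamp recordings are oversampled relative to CFTR gating (2 kHz
acquisition vs. gating rates of a few per second) and carry high-frequency
noise with little signal content.  Block-averaging decimation — the mean
over nonoverlapping blocks of ``factor`` samples — reduces white-noise
variance by the factor while preserving the slow gating steps, and by the
central limit theorem pushes the residual noise toward Gaussianity, which
is what the inference model assumes.

Recordings taken at negative holding potential have negative-going channel
openings; the emission model assumes closed level 0 and open level +A, so
``normalize`` flips polarity when needed and subtracts the closed-level
baseline.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .simulator import Trace

__all__ = ["RawTrace", "decimate", "normalize"]


@dataclasses.dataclass(frozen=True)
class RawTrace:
    """An unprocessed recording: samples at a known acquisition rate."""

    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        y = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", y)
        if y.ndim != 1 or y.size < 1:
            raise ValueError("raw trace must be a nonempty 1-D vector")
        if not self.sampling_rate > 0:
            raise ValueError("sampling rate must be positive (Hz)")


def decimate(raw: RawTrace, factor: int) -> Trace:
    """Block-averaging decimation by an integer factor.

    Output sample j is the mean of raw samples [j*factor, (j+1)*factor); a
    trailing partial block is discarded.  The output sampling interval is
    ``factor / sampling_rate``.
    """
    if factor < 1:
        raise ValueError("decimation factor must be >= 1")
    n = raw.samples.size
    if factor > n:
        raise ValueError(f"decimation factor {factor} exceeds trace length {n}")
    n_out = n // factor
    blocks = raw.samples[: n_out * factor].reshape(n_out, factor)
    return Trace(blocks.mean(axis=1), dt=factor / raw.sampling_rate)


def normalize(raw: RawTrace) -> RawTrace:
    """Flip polarity so openings are positive-going and zero the closed level.

    The two current levels are separated at the midpoint of (min, max); the
    cluster with the smaller absolute mean is taken as the closed level.
    If openings deflect negative, the trace is negated; the baseline
    (median of the closed-side samples) is then subtracted.  A single-level
    trace is returned unchanged with a warning.
    """
    y = raw.samples
    if y.max() - y.min() < 1e-12:
        warnings.warn("single-level trace: normalization is the identity", stacklevel=2)
        return raw
    mid = 0.5 * (y.min() + y.max())
    lower, upper = y[y <= mid], y[y > mid]
    # closed level = cluster nearer zero current
    if abs(lower.mean()) <= abs(upper.mean()):
        closed_is_lower = True
    else:
        closed_is_lower = False
    if not closed_is_lower:
        # openings are negative-going: flip so they become positive
        y = -y
        mid = -mid
        lower = y[y <= mid]
    baseline = float(np.median(lower))
    return RawTrace(y - baseline, sampling_rate=raw.sampling_rate)
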