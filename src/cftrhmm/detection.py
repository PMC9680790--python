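"""Closing detection: confidence-thresholded MAP states, event segmentation,
permissive/nonpermissive classification, and false-alarm / missed-detection
scoring.

The decision rule per sample is

    s_hat_k = argmax_s p(s_k = s | y)   if max_s p(s_k = s | y) > C,
              null                      otherwise,

with confidence threshold 0 <= C < 1 (C = 0 gives the plain MAP estimate).

A *closing* is a maximal run of closed-conductance samples flanked by open
samples on both sides.  Its label depends only on the flanking open-state
identities: permissive when the channel reopens in the same open state
(O1 -> ... -> O1 or O2 -> ... -> O2), nonpermissive when it closes from O2
and reopens as O1 — the only route, which traverses the irreversible ADP
release step C4 -> C1a.  Closings are segmented from the ungated MAP
sequence; the threshold enters through each event's ``confident`` flag
(true when both flanking open samples exceed C), which the scorer can use
as a filter.

Estimated events are matched one-to-one to ground-truth events by maximal
closed-interval overlap (at least one shared sample), greedily in
decreasing overlap.  With n_FA the number of estimated nonpermissive events
whose match is not a ground-truth nonpermissive closing (or that match
nothing) and n_MD the number of ground-truth nonpermissive closings not
matched by any estimated nonpermissive event,

    P_FA = n_FA / |L_E(np)|,    P_MD = n_MD / |L_GT(np)|.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .inference import PosteriorMatrix
from .kinetics import KineticScheme
from .simulator import StateSequence

__all__ = [
    "EstimateSequence",
    "ClosingEvent",
    "DetectionMetrics",
    "InvalidClosingError",
    "PERMISSIVE",
    "NONPERMISSIVE",
    "map_threshold",
    "extract_closings",
    "classify_by_adp_release",
    "score",
]

PERMISSIVE = "permissive"
NONPERMISSIVE = "nonpermissive"


class InvalidClosingError(ValueError):
    """Raised in strict mode for a flanking pair impossible under the scheme."""


@dataclasses.dataclass(frozen=True)
class EstimateSequence:
    """Thresholded MAP state estimates with their per-sample confidences.

    ``estimates[k]`` is None exactly where ``confidence[k] <= threshold``;
    ``map_labels`` keeps the ungated argmax everywhere (used for event
    segmentation).
    """

    map_labels: list[str]
    confidence: np.ndarray
    threshold: float
    states: tuple[str, ...]

    @property
    def estimates(self) -> list[str | None]:
        return [
            lab if conf > self.threshold else None
            for lab, conf in zip(self.map_labels, self.confidence)
        ]

    def __len__(self) -> int:
        return len(self.map_labels)


@dataclasses.dataclass(frozen=True)
class ClosingEvent:
    """One closed interval with its flanking open samples and label.

    The closed run occupies samples ``open_before_idx + 1`` through
    ``open_after_idx - 1`` inclusive.
    """

    open_before_idx: int
    open_after_idx: int
    initial_open_state: str
    final_open_state: str
    label: str
    confident: bool = True

    @property
    def closed_start(self) -> int:
        return self.open_before_idx + 1

    @property
    def closed_end(self) -> int:
        """Last closed sample index (inclusive)."""
        return self.open_after_idx - 1

    @property
    def n_closed_samples(self) -> int:
        return self.open_after_idx - self.open_before_idx - 1


@dataclasses.dataclass(frozen=True)
class DetectionMetrics:
    """Eq.-(8)-style error counts and rates for nonpermissive detection.

    ``p_fa`` / ``p_md`` are NaN when their denominator is zero; the
    ``*_defined`` flags make that explicit so sweep averages can exclude
    undefined runs.
    """

    n_fa: int
    n_md: int
    n_est_np: int
    n_gt_np: int
    n_est_total: int
    n_gt_total: int

    @property
    def pfa_defined(self) -> bool:
        return self.n_est_np > 0

    @property
    def pmd_defined(self) -> bool:
        return self.n_gt_np > 0

    @property
    def p_fa(self) -> float:
        return self.n_fa / self.n_est_np if self.pfa_defined else math.nan

    @property
    def p_md(self) -> float:
        return self.n_md / self.n_gt_np if self.pmd_defined else math.nan


def map_threshold(post: PosteriorMatrix, C: float) -> EstimateSequence:
    """Apply the confidence-thresholded MAP decision rule to a posterior."""
    if not 0 <= C < 1:
        raise ValueError(f"confidence threshold must be in [0, 1), got {C}")
    idx = post.map_indices()
    conf = post.confidence()
    labels = [post.states[i] for i in idx]
    return EstimateSequence(labels, conf, threshold=C, states=post.states)


def _label_pair(initial: str, final: str, strict: bool) -> str:
    if initial == final:
        return PERMISSIVE
    if strict and (initial, final) == ("O1", "O2"):
        raise InvalidClosingError(
            "closing flanked by (O1, O2): no closed path connects these "
            "without an intervening open state under the default scheme"
        )
    return NONPERMISSIVE


def extract_closings(
    seq: StateSequence | EstimateSequence | Sequence[str],
    scheme: KineticScheme,
    *,
    confidence: np.ndarray | None = None,
    threshold: float = 0.0,
    strict: bool = False,
) -> list[ClosingEvent]:
    """Segment a state sequence into complete closings and label each one.

    One event is produced per maximal run of closed-conductance states with
    an open-state sample on both sides; runs touching either sequence
    boundary are discarded (their flanking open state is unobserved).
    Labels use only the flanking open-state identities.  With ``strict``
    (intended for ground-truth paths) a flanking pair that is impossible
    under the scheme raises :class:`InvalidClosingError`; otherwise any
    differing pair is labeled nonpermissive.

    ``confidence``/``threshold`` set each event's ``confident`` flag (both
    flanking open samples strictly above the threshold).  When ``seq`` is an
    :class:`EstimateSequence`, its own confidences and threshold are used
    and segmentation runs on the ungated MAP labels.
    """
    if isinstance(seq, EstimateSequence):
        labels = seq.map_labels
        if confidence is None:
            confidence = seq.confidence
            threshold = seq.threshold
    elif isinstance(seq, StateSequence):
        labels = seq.labels
    else:
        labels = list(seq)
    cond = scheme.conductance_map
    open_idx = [k for k, lab in enumerate(labels) if cond[lab] == 1]
    events: list[ClosingEvent] = []
    for a, b in zip(open_idx, open_idx[1:]):
        if b == a + 1:
            continue  # no closed samples in between
        initial, final = labels[a], labels[b]
        label = _label_pair(initial, final, strict)
        conf_ok = True
        if confidence is not None:
            conf_ok = bool(confidence[a] > threshold and confidence[b] > threshold)
        events.append(
            ClosingEvent(
                open_before_idx=a,
                open_after_idx=b,
                initial_open_state=initial,
                final_open_state=final,
                label=label,
                confident=conf_ok,
            )
        )
    return events


def classify_by_adp_release(
    seq: StateSequence | Sequence[str], event: ClosingEvent
) -> str:
    """Label a ground-truth closing by whether it contains a C4 -> C1a step.

    Independent of the flanking-open-state rule; on topology-respecting
    paths (e.g. the embedded jump chain) the two definitions coincide
    exactly.  On a dt-sampled chain they can disagree on the rare closings
    where several transitions fall between consecutive samples.
    """
    labels = seq.labels if isinstance(seq, StateSequence) else seq
    window = labels[event.open_before_idx : event.open_after_idx + 1]
    for prev, cur in zip(window, window[1:]):
        if (prev, cur) == ("C4", "C1a"):
            return NONPERMISSIVE
    return PERMISSIVE


def _match_events(
    gt_events: list[ClosingEvent], est_events: list[ClosingEvent]
) -> dict[int, int]:
    """Greedy one-to-one matching est->gt by decreasing closed-interval overlap."""
    pairs = []
    for ei, e in enumerate(est_events):
        for gi, g in enumerate(gt_events):
            lo = max(e.closed_start, g.closed_start)
            hi = min(e.closed_end, g.closed_end)
            overlap = hi - lo + 1
            if overlap >= 1:
                pairs.append((-overlap, e.closed_start, g.closed_start, ei, gi))
    pairs.sort()
    matched_est: dict[int, int] = {}
    used_gt: set[int] = set()
    for _, _, _, ei, gi in pairs:
        if ei in matched_est or gi in used_gt:
            continue
        matched_est[ei] = gi
        used_gt.add(gi)
    return matched_est


def score(
    gt_events: list[ClosingEvent],
    est_events: list[ClosingEvent],
    use_confident_only: bool = False,
) -> DetectionMetrics:
    """Score estimated closings against ground truth (false alarms / misses).

    Both lists must come from equal-length sequences on the same time base.
    With ``use_confident_only``, estimated events whose ``confident`` flag
    is false are dropped before matching (the confidence-gated detector).
    """
    est = [e for e in est_events if e.confident] if use_confident_only else list(est_events)
    matched = _match_events(gt_events, est)

    n_fa = 0
    gt_np_hit: set[int] = set()
    for ei, e in enumerate(est):
        if e.label != NONPERMISSIVE:
            continue
        gi = matched.get(ei)
        if gi is None or gt_events[gi].label != NONPERMISSIVE:
            n_fa += 1
        else:
            gt_np_hit.add(gi)
    gt_np = [gi for gi, g in enumerate(gt_events) if g.label == NONPERMISSIVE]
    n_md = sum(1 for gi in gt_np if gi not in gt_np_hit)

    return DetectionMetrics(
        n_fa=n_fa,
        n_md=n_md,
        n_est_np=sum(1 for e in est if e.label == NONPERMISSIVE),
        n_gt_np=len(gt_np),
        n_est_total=len(est),
        n_gt_total=len(gt_events),
    )
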