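"""MAP thresholding, closing segmentation/labels, and error-rate scoring."""

import numpy as np
import pytest

import cftrhmm as ch
from cftrhmm.detection import (
    ClosingEvent,
    InvalidClosingError,
    NONPERMISSIVE,
    PERMISSIVE,
    classify_by_adp_release,
    extract_closings,
    map_threshold,
    score,
)
from cftrhmm.inference import PosteriorMatrix
from cftrhmm.kinetics import embedded_jump_chain


def make_posterior(rows, states):
    rows = np.asarray(rows, dtype=float)
    return PosteriorMatrix(rows, log_likelihood=0.0, states=states)


class TestMapThreshold:
    def test_confident_row_keeps_argmax(self, scheme):
        post = make_posterior([[0.9, 0.1, 0, 0, 0, 0, 0]], scheme.state_names)
        est = map_threshold(post, 0.8)
        assert est.estimates == ["C1a"]

    def test_unconfident_row_is_null(self, scheme):
        post = make_posterior([[0.6, 0.4, 0, 0, 0, 0, 0]], scheme.state_names)
        est = map_threshold(post, 0.8)
        assert est.estimates == [None]
        assert est.map_labels == ["C1a"]  # ungated argmax retained

    def test_zero_threshold_has_no_nulls(self, scheme):
        rng = np.random.default_rng(0)
        rows = rng.dirichlet(np.ones(7), size=50)
        est = map_threshold(make_posterior(rows, scheme.state_names), 0.0)
        assert all(e is not None for e in est.estimates)

    @pytest.mark.parametrize("C", [-0.1, 1.0, 1.5])
    def test_threshold_domain(self, scheme, C):
        post = make_posterior([[1, 0, 0, 0, 0, 0, 0]], scheme.state_names)
        with pytest.raises(ValueError):
            map_threshold(post, C)


class TestExtractClosings:
    def test_short_permissive_closing(self, scheme):
        events = extract_closings(["O1", "C2", "C2", "O1"], scheme)
        assert len(events) == 1
        e = events[0]
        assert (e.initial_open_state, e.final_open_state) == ("O1", "O1")
        assert e.label == PERMISSIVE
        assert (e.open_before_idx, e.open_after_idx) == (0, 3)

    def test_nonpermissive_closing_through_adp_release(self, scheme):
        seq = ["O2", "C3", "C4", "C1a", "C1b", "C2", "O1"]
        events = extract_closings(seq, scheme)
        assert len(events) == 1
        assert events[0].label == NONPERMISSIVE
        assert classify_by_adp_release(seq, events[0]) == NONPERMISSIVE

    def test_boundary_runs_discarded(self, scheme):
        assert extract_closings(["C2", "C2", "O1", "O1"], scheme) == []
        assert extract_closings(["O1", "O1", "C2", "C2"], scheme) == []
        assert extract_closings(["C2", "C2"], scheme) == []

    def test_adjacent_open_samples_produce_no_event(self, scheme):
        assert extract_closings(["O1", "O2", "O2"], scheme) == []

    def test_strict_mode_rejects_impossible_flanks(self, scheme):
        seq = ["O1", "C2", "O2"]
        with pytest.raises(InvalidClosingError):
            extract_closings(seq, scheme, strict=True)
        # non-strict follows the different-flanks-means-nonpermissive rule
        events = extract_closings(seq, scheme)
        assert events[0].label == NONPERMISSIVE

    def test_confidence_gating_flags_flanks(self, scheme):
        seq = ["O1", "C2", "O1", "C2", "O1"]
        conf = np.array([0.95, 0.5, 0.95, 0.9, 0.7])
        events = extract_closings(seq, scheme, confidence=conf, threshold=0.8)
        assert [e.confident for e in events] == [True, False]

    def test_estimate_sequence_input_uses_ungated_map(self, scheme):
        rows = np.zeros((4, 7))
        rows[0, scheme.index("O1")] = 0.95
        rows[1, scheme.index("C2")] = 0.55  # below C, but still segments
        rows[1, scheme.index("C1b")] = 0.45
        rows[2, scheme.index("C2")] = 0.9
        rows[3, scheme.index("O1")] = 0.85
        rows /= rows.sum(axis=1, keepdims=True)
        est = map_threshold(make_posterior(rows, scheme.state_names), 0.8)
        events = extract_closings(est, scheme)
        assert len(events) == 1
        assert events[0].confident  # flanks are both above C


class TestEquivalenceOfDefinitions:
    def test_flanking_label_equals_adp_release_label_on_valid_paths(self, scheme):
        # the embedded jump chain only takes real edges, so every path is valid
        P = embedded_jump_chain(ch.rate_matrix(scheme, 1e-3))
        init = ch.stationary_distribution(P)
        s = ch.sample_states(P, 200_000, init, seed=17)
        events = extract_closings(s, scheme, strict=True)
        assert len(events) > 1000
        labels = s.labels
        assert all(classify_by_adp_release(labels, e) == e.label for e in events)


class TestScore:
    def _events(self, spec):
        """spec: list of (closed_start, closed_end, label[, confident])."""
        out = []
        for item in spec:
            start, end, label = item[:3]
            conf = item[3] if len(item) > 3 else True
            initial, final = ("O2", "O1") if label == NONPERMISSIVE else ("O1", "O1")
            out.append(
                ClosingEvent(
                    open_before_idx=start - 1,
                    open_after_idx=end + 1,
                    initial_open_state=initial,
                    final_open_state=final,
                    label=label,
                    confident=conf,
                )
            )
        return out

    def test_identical_lists_are_perfect(self, scheme):
        gt = self._events([(2, 5, NONPERMISSIVE), (10, 12, PERMISSIVE), (20, 30, NONPERMISSIVE)])
        m = score(gt, gt)
        assert m.n_fa == 0 and m.n_md == 0
        assert m.p_fa == 0.0 and m.p_md == 0.0

    def test_mixed_matching_arithmetic(self):
        # 2 gt nonpermissive; est has 2 nonpermissive: one overlaps a gt
        # nonpermissive, the other overlaps a gt permissive closing
        gt = self._events([(2, 5, NONPERMISSIVE), (10, 14, PERMISSIVE), (20, 25, NONPERMISSIVE)])
        est = self._events([(3, 6, NONPERMISSIVE), (11, 13, NONPERMISSIVE)])
        m = score(gt, est)
        assert m.n_fa == 1 and m.p_fa == pytest.approx(0.5)
        assert m.n_md == 1 and m.p_md == pytest.approx(0.5)

    def test_unmatched_estimate_is_false_alarm(self):
        gt = self._events([(2, 5, NONPERMISSIVE)])
        est = self._events([(2, 5, NONPERMISSIVE), (50, 60, NONPERMISSIVE)])
        m = score(gt, est)
        assert m.n_fa == 1 and m.p_fa == pytest.approx(0.5)
        assert m.n_md == 0

    def test_empty_estimate_list(self):
        gt = self._events([(2, 5, NONPERMISSIVE), (10, 12, PERMISSIVE)])
        m = score(gt, [])
        assert not m.pfa_defined and np.isnan(m.p_fa)
        assert m.pmd_defined and m.p_md == 1.0

    def test_confident_only_filters(self):
        gt = self._events([(2, 5, NONPERMISSIVE)])
        est = self._events([(2, 5, NONPERMISSIVE, False)])
        gated = score(gt, est, use_confident_only=True)
        assert gated.n_est_np == 0 and not gated.pfa_defined and gated.p_md == 1.0
        ungated = score(gt, est, use_confident_only=False)
        assert ungated.p_fa == 0.0 and ungated.p_md == 0.0

    def test_one_to_one_matching_by_largest_overlap(self):
        # one long gt closing vs two est closings: only one can match
        gt = self._events([(10, 30, NONPERMISSIVE)])
        est = self._events([(10, 25, NONPERMISSIVE), (27, 30, NONPERMISSIVE)])
        m = score(gt, est)
        assert m.n_fa == 1  # the smaller-overlap event finds no partner
        assert m.n_md == 0


class TestConfidenceMonotonicity:
    def test_raising_threshold_never_adds_confident_events(self, scheme, Q_1mM, pi_1mM):
        em = ch.EmissionModel(1.0, 0.02)
        _, tr = ch.simulate_trace(scheme, 1e-3, 0.01, 10_000, em, 23)
        post, _ = ch.forward_backward(tr, Q_1mM, em, pi_1mM, scheme)
        est = map_threshold(post, 0.0)
        counts = []
        for C in (0.0, 0.2, 0.4, 0.6, 0.8, 0.95):
            events = extract_closings(est, scheme, confidence=est.confidence, threshold=C)
            counts.append(sum(1 for e in events if e.confident))
        assert all(a >= b for a, b in zip(counts, counts[1:]))
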