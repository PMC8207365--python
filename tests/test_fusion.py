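import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ethopipe.ethogram import BehaviorLabel, IntervalTimeline
from ethopipe.fusion import (
    DEFAULT_RULES,
    TransitionRule,
    apply_rules,
    decide,
    fuse_streams,
    inject_absence,
    load_rules_yaml,
    rolling_average,
    rule_violations,
)

from conftest import ABS, LHD, LHU, S, random_label_sequence


class TestFuseStreams:
    def test_componentwise_mean(self):
        out = fuse_streams([0.8, 0.1, 0.1], [0.6, 0.2, 0.2])
        np.testing.assert_allclose(out, [0.7, 0.15, 0.15])

    def test_idempotent_on_equal_inputs(self):
        p = np.array([0.2, 0.3, 0.5])
        np.testing.assert_allclose(fuse_streams(p, p), p)

    def test_output_normalized(self, rng):
        for _ in range(100):
            out = fuse_streams(rng.dirichlet(np.ones(3)), rng.dirichlet(np.ones(3)))
            assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            fuse_streams([0.5, 0.5], [0.3, 0.3, 0.4])

    def test_batched(self, rng):
        a = rng.dirichlet(np.ones(4), size=10)
        b = rng.dirichlet(np.ones(4), size=10)
        np.testing.assert_allclose(fuse_streams(a, b), (a + b) / 2)


class TestRollingAverage:
    def test_constant_unchanged(self):
        seq = np.tile([0.2, 0.3, 0.5], (10, 1))
        np.testing.assert_allclose(rolling_average(seq), seq)

    def test_center_element(self):
        seq = np.array([[1, 0, 0], [0, 1, 0], [1, 0, 0]], dtype=float)
        out = rolling_average(seq, window=3)
        np.testing.assert_allclose(out[1], [2 / 3, 1 / 3, 0])

    def test_truncated_boundary(self):
        seq = np.array([[1, 0, 0], [0, 1, 0], [1, 0, 0]], dtype=float)
        out = rolling_average(seq, window=3)
        np.testing.assert_allclose(out[0], [0.5, 0.5, 0.0])  # mean of rows 0, 1

    def test_empty(self):
        assert rolling_average(np.empty((0, 3))).size == 0

    def test_length_conserved_and_normalized(self, rng):
        for window in (1, 3, 5, 7):
            seq = rng.dirichlet(np.ones(4), size=25)
            out = rolling_average(seq, window=window)
            assert out.shape == seq.shape
            np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_window_one_is_identity(self, rng):
        seq = rng.dirichlet(np.ones(3), size=9)
        np.testing.assert_allclose(rolling_average(seq, window=1), seq)

    @pytest.mark.parametrize("window", [0, 2, 4, -1])
    def test_even_or_nonpositive_window_rejected(self, window):
        with pytest.raises(ValueError):
            rolling_average(np.ones((3, 3)) / 3, window=window)


class TestInjectAbsence:
    def test_fully_present(self):
        out = inject_absence(np.array([0.7, 0.2, 0.1]), 1.0)
        np.testing.assert_allclose(out, [0.7, 0.2, 0.1, 0.0])

    def test_fully_absent(self):
        np.testing.assert_allclose(inject_absence(None, 0.0), [0, 0, 0, 1])

    def test_partial_detection(self):
        out = inject_absence(np.array([1.0, 0.0, 0.0]), 4 / 7)
        np.testing.assert_allclose(out, [4 / 7, 0, 0, 3 / 7])

    def test_normalized(self, rng):
        for _ in range(100):
            out = inject_absence(rng.dirichlet(np.ones(3)), rng.uniform(1e-6, 1))
            assert out.sum() == pytest.approx(1.0, abs=1e-9)

    def test_missing_probs_with_detection_rejected(self):
        with pytest.raises(ValueError):
            inject_absence(None, 0.5)


class TestDecide:
    def test_unique_max(self):
        assert decide([0.1, 0.7, 0.1, 0.1]) is LHU

    def test_tie_breaks_to_smaller_label(self):
        assert decide([0.4, 0.4, 0.1, 0.1]) is S
        assert decide([0.0, 0.5, 0.5, 0.0]) is LHU

    def test_absent(self):
        assert decide([0, 0, 0, 1]) is ABS


class TestTransitionRule:
    def test_default_rule_set(self):
        assert len(DEFAULT_RULES) == 6
        minima = [r.min_intervals for r in DEFAULT_RULES]
        assert minima == [3, 6, 6, 25, 25, 50]
        assert DEFAULT_RULES[5].current is ABS

    def test_empty_prev_set_rejected(self):
        with pytest.raises(ValueError):
            TransitionRule(frozenset(), LHD, frozenset({S}), 3)

    def test_min_intervals_at_least_one(self):
        with pytest.raises(ValueError):
            TransitionRule(frozenset({S}), LHD, frozenset({S}), 0)

    def test_yaml_defaults_match_builtin(self):
        import importlib.resources

        path = importlib.resources.files("ethopipe") / "data" / "default_rules.yaml"
        assert load_rules_yaml(path) == list(DEFAULT_RULES)


def tl(labels):
    return IntervalTimeline(list(labels))


class TestApplyRules:
    def test_short_lhd_between_standing_and_lhu(self):
        before = tl([S] * 10 + [LHD] * 2 + [LHU] * 10)
        after = apply_rules(before)
        assert after.labels == [S] * 12 + [LHU] * 10

    def test_short_absence_swallowed(self):
        before = tl([S] * 100 + [ABS] * 30 + [S] * 100)
        assert apply_rules(before).labels == [S] * 230

    def test_long_enough_phase_survives(self):
        labels = [S] * 100 + [ABS] * 50 + [S] * 100
        assert apply_rules(tl(labels)).labels == labels

    def test_fixpoint_timeline_unchanged(self):
        labels = [S] * 30 + [LHU] * 30 + [LHD] * 30 + [LHU] * 30
        assert apply_rules(tl(labels)).labels == labels

    def test_boundary_phases_never_replaced(self):
        # short LHD at the night edge has no previous phase
        labels = [LHD] * 2 + [S] * 50
        assert apply_rules(tl(labels)).labels == labels

    def test_replacement_target_is_previous_label(self):
        # rule 2: prev LHD, current short LHU, next standing -> becomes LHD
        before = tl([LHD] * 10 + [LHU] * 3 + [S] * 30)
        assert apply_rules(before).labels == [LHD] * 13 + [S] * 30

    def test_cascading_merge(self):
        # swallowing the short LHU exposes a short standing phase
        before = tl([LHD] * 10 + [LHU] * 2 + [S] * 2 + [LHD] * 10)
        assert apply_rules(before).labels == [LHD] * 24

    def test_idempotent(self, rng):
        for _ in range(200):
            before = tl(random_label_sequence(rng, int(rng.integers(0, 80))))
            once = apply_rules(before)
            twice = apply_rules(once)
            assert twice.labels == once.labels

    def test_length_conserved(self, rng):
        for _ in range(200):
            labels = random_label_sequence(rng, int(rng.integers(0, 80)))
            assert len(apply_rules(tl(labels))) == len(labels)

    def test_no_violations_after(self, rng):
        for _ in range(200):
            after = apply_rules(tl(random_label_sequence(rng, int(rng.integers(0, 80)))))
            assert rule_violations(after) == []

    def test_max_passes_zero_returns_input(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            before = tl([S] * 10 + [LHD] * 2 + [LHU] * 10)
            assert apply_rules(before, max_passes=0).labels == before.labels

    def test_empty_and_single_phase(self):
        assert apply_rules(tl([])).labels == []
        assert apply_rules(tl([LHD] * 5)).labels == [LHD] * 5


class TestRuleViolations:
    def test_detects_short_interior_phase(self):
        v = rule_violations(tl([S] * 10 + [LHD] * 2 + [LHU] * 10))
        assert len(v) == 1
        assert v[0][1].min_intervals == 3

    def test_clean_timeline(self):
        assert rule_violations(tl([S] * 30 + [LHU] * 30 + [S] * 30)) == []


probs3 = st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3).map(
    lambda xs: np.array(xs) / np.sum(xs)
)


@given(st.lists(probs3, min_size=1, max_size=30))
def test_probability_conservation_through_chain(vectors):
    """fuse -> roll -> inject stays normalized end to end."""
    p = np.array(vectors)
    fused = fuse_streams(p, p[::-1])
    rolled = rolling_average(fused, window=3)
    for row in rolled:
        four = inject_absence(row, 0.9)
        assert four.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(four >= 0)
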