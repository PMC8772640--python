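"""Task-difficulty labelling: counts, entropy, discretization, fusion."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opstate.difficulty import (
    Level,
    active_counts,
    compute_td_series,
    default_rule_table,
    discretize,
    fuse_difficulty,
    spatial_entropy,
)

from conftest import make_log


class TestActiveCounts:
    def test_empty_log(self):
        assert active_counts(make_log([]), 10.0) == (0, 0)

    def test_half_open_interval(self):
        log = make_log([(10.0, 20.0, "target", 0, 0)])
        assert active_counts(log, 10.0) == (1, 0)
        assert active_counts(log, 19.99) == (1, 0)
        assert active_counts(log, 20.0) == (0, 0)

    def test_matches_brute_force_scan(self, rng):
        rows = []
        for _ in range(50):
            a = rng.uniform(0, 30)
            rows.append((a, a + rng.uniform(0, 15),
                         rng.choice(["target", "message"]), 0, rng.integers(0, 4)))
        log = make_log(rows)
        for t in rng.uniform(0, 40, size=20):
            n1 = sum(1 for r in rows if r[2] == "target" and r[0] <= t < r[1])
            n2 = sum(1 for r in rows if r[2] == "message" and r[0] <= t < r[1])
            assert active_counts(log, t) == (n1, n2)

    def test_outside_span_rejected(self):
        log = make_log([(0.0, 5.0, "target", 0, 0)])
        with pytest.raises(ValueError):
            active_counts(log, 50.0, span=(0.0, 30.0))


class TestSpatialEntropy:
    def test_known_values(self):
        assert spatial_entropy([7, 0, 0, 0, 0, 0, 0, 0]) == 0.0
        assert spatial_entropy(np.ones(8) / 8) == pytest.approx(np.log(8))
        assert spatial_entropy([0.5, 0.5, 0, 0]) == pytest.approx(np.log(2))

    def test_empty_screen_is_zero(self):
        assert spatial_entropy(np.zeros(8)) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            spatial_entropy([0.5, -0.1, 0.6])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.integers(min_value=0, max_value=30), min_size=2, max_size=8))
    def test_bounds_and_oracle(self, counts):
        h = spatial_entropy(counts)
        assert 0.0 <= h <= np.log(len(counts)) + 1e-12
        total = sum(counts)
        if total:
            expected = -sum(c / total * np.log(c / total) for c in counts if c)
            assert h == pytest.approx(expected)


class TestDiscretize:
    @pytest.mark.parametrize("n1,expected", [
        (0, Level.LOW), (5, Level.LOW), (6, Level.MEDIUM),
        (11, Level.MEDIUM), (12, Level.HIGH),
    ])
    def test_n1_thresholds(self, n1, expected):
        assert discretize(n1, 0, 0.0)[0] == expected

    @pytest.mark.parametrize("n2,expected", [(2, Level.LOW), (3, Level.HIGH)])
    def test_n2_thresholds(self, n2, expected):
        assert discretize(0, n2, 0.0)[1] == expected

    @pytest.mark.parametrize("h,expected", [
        (0.45, Level.LOW), (0.46, Level.MEDIUM), (1.0, Level.MEDIUM), (1.01, Level.HIGH),
    ])
    def test_entropy_thresholds(self, h, expected):
        assert discretize(0, 0, h)[2] == expected


# The full 18-cell fusion table, enumerated by hand from the documented
# rules: high iff (N1d high, N2d high, Entropyd >= medium); low iff at
# most one component exceeds its minimum; medium otherwise.
EXPECTED_FUSION = {
    (Level.LOW, Level.LOW, Level.LOW): 1,
    (Level.MEDIUM, Level.LOW, Level.LOW): 1,
    (Level.HIGH, Level.LOW, Level.LOW): 1,
    (Level.LOW, Level.HIGH, Level.LOW): 1,
    (Level.LOW, Level.LOW, Level.MEDIUM): 1,
    (Level.LOW, Level.LOW, Level.HIGH): 1,
    (Level.MEDIUM, Level.HIGH, Level.LOW): 2,
    (Level.HIGH, Level.HIGH, Level.LOW): 2,
    (Level.MEDIUM, Level.LOW, Level.MEDIUM): 2,
    (Level.MEDIUM, Level.LOW, Level.HIGH): 2,
    (Level.HIGH, Level.LOW, Level.MEDIUM): 2,
    (Level.HIGH, Level.LOW, Level.HIGH): 2,
    (Level.LOW, Level.HIGH, Level.MEDIUM): 2,
    (Level.LOW, Level.HIGH, Level.HIGH): 2,
    (Level.MEDIUM, Level.HIGH, Level.MEDIUM): 2,
    (Level.MEDIUM, Level.HIGH, Level.HIGH): 2,
    (Level.HIGH, Level.HIGH, Level.MEDIUM): 3,
    (Level.HIGH, Level.HIGH, Level.HIGH): 3,
}


class TestFusion:
    def test_printed_high_rule(self):
        assert fuse_difficulty(Level.HIGH, Level.HIGH, Level.MEDIUM) == 3

    def test_minimal_state_is_low(self):
        assert fuse_difficulty(Level.LOW, Level.LOW, Level.LOW) == 1

    def test_full_table_matches_enumeration(self):
        for state, td in EXPECTED_FUSION.items():
            assert fuse_difficulty(*state) == td, state
        assert len(EXPECTED_FUSION) == 18

    def test_monotone_in_every_component(self):
        states = list(EXPECTED_FUSION)
        for a, b in itertools.product(states, states):
            if all(x <= y for x, y in zip(a, b)):
                assert fuse_difficulty(*a) <= fuse_difficulty(*b)

    def test_custom_rule_table_respected(self):
        table = {k: 2 for k in default_rule_table()}
        assert fuse_difficulty(Level.LOW, Level.LOW, Level.LOW, rule_table=table) == 2


class TestTdSeries:
    def test_no_stimuli_means_lowest_difficulty(self):
        td = compute_td_series(make_log([]), span=60.0)
        assert len(td) == 60
        assert (td["td"] == 1).all()

    def test_manual_trace(self):
        # 12 targets spread over 6 zones and 3 messages, alive on [2, 30):
        # N1 = 12 (high), N2 = 3 (high), entropy = ln 6 (high) -> TD3.
        rows = []
        for z in range(6):
            for _ in range(2):
                rows.append((2.0, 30.0, "target", z // 4, z % 4))
        rows += [(2.0, 30.0, "message", 0, 0)] * 3
        td = compute_td_series(make_log(rows), span=40.0)
        at5 = td[td["t_s"] == 5.0].iloc[0]
        assert at5["n1"] == 12 and at5["n2"] == 3
        assert at5["entropy"] == pytest.approx(np.log(6))
        assert at5["td"] == 3
        assert td[td["t_s"] == 0.0]["td"].iloc[0] == 1  # before anything appears
        assert td[td["t_s"] == 35.0]["td"].iloc[0] == 1  # after removal

    def test_output_length_equals_span(self):
        td = compute_td_series(make_log([]), span=123.0)
        assert len(td) == 123

    def test_record_order_irrelevant(self, rng):
        rows = [(rng.uniform(0, 50), 0, "target", 0, int(rng.integers(0, 4)))
                for _ in range(30)]
        rows = [(a, a + 20.0, k, r, c) for (a, _, k, r, c) in rows]
        log = make_log(rows)
        shuffled = log.sample(frac=1, random_state=3).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            compute_td_series(log, span=80.0), compute_td_series(shuffled, span=80.0)
        )
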