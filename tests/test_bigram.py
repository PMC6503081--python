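"""Bigram statistics and the information measures H, h, h-bar."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from chunklearn import SENTINEL, BigramModel, mean_ic


class TestCounting:
    def test_first_update_counts_the_sentinel_pair(self):
        m = BigramModel()
        m.update(SENTINEL, "a")
        assert m.counts[SENTINEL]["a"] == 1

    def test_hand_enumerated_counts_on_the_toy(self, toy_ids):
        # pairs: ^a, ab, bd, da, ab, be
        m = BigramModel.from_sequence(toy_ids)
        assert m.counts["a"]["b"] == 2
        assert m.counts["b"]["d"] == 1
        assert m.counts["b"]["e"] == 1
        assert m.counts["d"]["a"] == 1

    def test_updates_are_incremental(self, toy_ids):
        prefix = BigramModel.from_sequence(toy_ids[:-1])
        full = BigramModel.from_sequence(toy_ids)
        diff = [
            (p, s)
            for p in set(prefix.counts) | set(full.counts)
            for s in set(prefix.counts[p]) | set(full.counts[p])
            if prefix.counts[p][s] != full.counts[p][s]
        ]
        assert diff == [("b", "e")]

    def test_online_counts_equal_static_counts_after_full_pass(self, fig_ids):
        static = BigramModel.from_sequence(fig_ids, mode="static")
        online = BigramModel.from_sequence(fig_ids, mode="online")
        assert {p: dict(c) for p, c in static.counts.items()} == \
               {p: dict(c) for p, c in online.counts.items()}


class TestDistribution:
    def test_hand_counted_distribution(self, toy_ids):
        m = BigramModel.from_sequence(toy_ids)
        assert m.distribution("b") == {"d": 0.5, "e": 0.5}
        assert m.distribution("a") == {"b": 1.0}

    def test_unseen_context_is_undefined_not_empty(self, toy_ids):
        m = BigramModel.from_sequence(toy_ids)
        assert m.distribution("e") is None  # e never opens a bigram
        assert m.entropy("e") is None

    def test_distributions_sum_to_one(self, fig_ids):
        m = BigramModel.from_sequence(fig_ids)
        for ctx in "bcde":
            dist = m.distribution(ctx)
            assert dist is not None
            assert math.isclose(sum(dist.values()), 1.0, abs_tol=1e-12)


class TestInformationMeasures:
    @pytest.mark.parametrize("dist, expected", [
        ({"d": 0.5, "e": 0.5}, 1.0),
        ({"b": 1.0}, 0.0),
        ({"w": 0.25, "x": 0.25, "y": 0.25, "z": 0.25}, 2.0),
    ])
    def test_entropy_of_simple_distributions(self, dist, expected):
        seq = [s for s, p in dist.items() for _ in range(int(p * 4))]
        m = BigramModel()
        for s in seq:
            m.update("c", s)
        assert m.entropy("c") == pytest.approx(expected)

    def test_information_content_of_certain_and_even_transitions(self, toy_ids):
        m = BigramModel.from_sequence(toy_ids)
        assert m.information_content("a", "b") == 0.0  # p = 1
        assert m.information_content("b", "d") == pytest.approx(1.0)  # p = 1/2

    def test_unseen_transition_is_infinite_in_static_mode(self, toy_ids):
        m = BigramModel.from_sequence(toy_ids)
        assert m.information_content("a", "e") == math.inf

    def test_toy_h_profile(self, toy_ids):
        m = BigramModel.from_sequence(toy_ids)
        assert m.h_profile(toy_ids) == pytest.approx([0, 0, 1, 0, 0, 1])

    def test_smoothing_keeps_online_predictions_defined(self):
        m = BigramModel(mode="online")
        m.update(SENTINEL, "a")
        assert m.information_content("q", "a") is not None


class TestMeanInformationContent:
    def test_toy_hbar_is_one_third(self, toy_ids):
        hbar, n_undef = mean_ic(toy_ids)
        assert hbar == pytest.approx(1 / 3)
        assert n_undef == 0

    def test_constant_sequence_has_zero_hbar(self):
        assert mean_ic(list("aaaa"))[0] == 0.0

    def test_single_category_collapse_zeroes_hbar(self, toy_ids):
        assert mean_ic(["p" for _ in toy_ids])[0] == 0.0

    def test_empty_layer_is_undefined(self):
        with pytest.raises(ValueError):
            mean_ic([])


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from("abcd"), min_size=1, max_size=50))
def test_hbar_matches_brute_force_bit_tally(ids):
    """Static h-bar equals (total bits of the sequence under the model) /
    (number of moments), tallied moment by moment."""
    m = BigramModel.from_sequence(ids)
    prev = SENTINEL
    total = 0.0
    for s in ids:
        total += -math.log2(m.counts[prev][s] / m.totals[prev])
        prev = s
    assert mean_ic(ids)[0] == pytest.approx(total / len(ids), abs=1e-12)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from("abcde"), min_size=2, max_size=40))
def test_entropy_is_bounded_by_log_alphabet_size(ids):
    m = BigramModel.from_sequence(ids)
    bound = m.max_entropy()
    for ctx in set(ids):
        H = m.entropy(ctx)
        if H is not None:
            assert -1e-12 <= H <= bound + 1e-12
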