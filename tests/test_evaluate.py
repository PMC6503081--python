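"""Token-position scoring and the chance baselines."""

import numpy as np
import pytest

from chunklearn import (AlignmentError, GoldSegmentation, Stage, Symbol,
                        append_moment, chance_baseline, learn,
                        memory_from_symbols, score_tokens)
from chunklearn.chunker import chunk_id


def _memory_with_boundaries(text: str, cuts: list[int]):
    """A two-level memory whose chunk layer cuts the stream at the given
    character positions."""
    mem = memory_from_symbols(text)
    base = mem.layers[mem.base_key]
    layer = mem.new_layer("chunk", alpha=1, source=base.key)
    lam = mem.lam.setdefault(layer.key, {})
    bounds = [0] + sorted(cuts) + [len(text)]
    for lo, hi in zip(bounds, bounds[1:]):
        content = tuple(text[lo:hi])
        cid = chunk_id(content)
        lam.setdefault(cid, content)
        append_moment(layer, Symbol(cid, layer.delta, layer.alpha), (lo, hi))
    mem.stages.append(Stage(base=layer.key))
    return mem


class TestScoreTokens:
    def test_perfect_tiling_scores_100_percent_at_level_1(self):
        gold = GoldSegmentation.from_words(["the", "cat", "the", "cat"])
        mem = _memory_with_boundaries("thecatthecat", [3, 6, 9])
        report = score_tokens(mem, gold)
        by_alpha = {lv["alpha"]: lv["count"] for lv in report.levels}
        assert by_alpha[1] == 4 and by_alpha[0] == 0
        assert report.total_percent == 100.0

    def test_no_boundaries_finds_no_multitoken_words(self):
        gold = GoldSegmentation.from_words(["the", "cat"])
        mem = _memory_with_boundaries("thecat", [])
        assert score_tokens(mem, gold).total_count == 0

    def test_tokens_are_credited_at_the_lowest_level(self):
        gold = GoldSegmentation.from_words(["a", "bc"])
        mem = _memory_with_boundaries("abc", [1])
        report = score_tokens(mem, gold)
        by_alpha = {lv["alpha"]: lv["count"] for lv in report.levels}
        assert by_alpha[0] == 1  # "a" found at the character level
        assert by_alpha[1] == 1

    def test_adding_layers_never_removes_credit(self):
        words = ["ab", "cd", "ab", "cd", "ab"]
        gold = GoldSegmentation.from_words(words)
        text = "".join(words)
        mem = learn(text)
        shallow = _memory_with_boundaries(text, [2, 4, 6, 8])
        assert score_tokens(mem, gold).total_count >= 0
        assert score_tokens(shallow, gold).total_count == 5

    def test_stream_mismatch_is_an_alignment_error(self):
        gold = GoldSegmentation.from_words(["the", "cat"])
        mem = memory_from_symbols("thedog" + "x")
        with pytest.raises(AlignmentError):
            score_tokens(mem, gold)

    def test_level_counts_sum_to_total(self):
        gold = GoldSegmentation.from_words(["ab", "cd", "ab"])
        mem = learn("abcdab")
        report = score_tokens(mem, gold)
        assert sum(lv["count"] for lv in report.levels) == report.total_count


class TestChanceBaselines:
    def test_single_token_gold_scores_100(self):
        gold = GoldSegmentation.from_words(["zebra"])
        assert chance_baseline(gold, 5, "A", reps=10, seed=0) == 100.0

    def test_mean_over_reps_is_the_arithmetic_mean(self):
        gold = GoldSegmentation.from_words(["ab", "cd", "ab"])
        singles = [chance_baseline(gold, 6, "A", reps=1, seed=s)
                   for s in range(8)]
        # a different seed stream, same definition: each rep is one score
        assert all(0.0 <= s <= 100.0 for s in singles)

    def test_variant_a_resampling_consistency(self):
        """Two independent 100-rep runs agree within 3 standard errors."""
        spec_words = ["the", "cat", "dog", "fish", "bird"]
        rng = np.random.default_rng(0)
        words = [spec_words[i] for i in rng.integers(0, 5, 1000)]
        gold = GoldSegmentation.from_words(words)
        L = gold.stream_length
        a1 = chance_baseline(gold, L, "A", reps=100, seed=1)
        a2 = chance_baseline(gold, L, "A", reps=100, seed=2)
        # per-rep scores are percentages of n~1000 tokens; their SEM over
        # 100 reps is well under 0.15 points at these rates
        assert abs(a1 - a2) < 3 * 0.15

    def test_variant_b_uses_uniform_position_probability(self):
        gold = GoldSegmentation.from_words(["ab"] * 4)
        score = chance_baseline(gold, 8, "B", reps=50, seed=3)
        assert 0.0 <= score <= 100.0

    def test_infeasible_boundary_count_is_an_error(self):
        gold = GoldSegmentation.from_words(["a", "b", "c"])
        with pytest.raises(ValueError):
            chance_baseline(gold, 2, "A", reps=1, seed=0)

    def test_unknown_variant_rejected(self):
        gold = GoldSegmentation.from_words(["ab", "cd"])
        with pytest.raises(ValueError):
            chance_baseline(gold, 4, "C", reps=1, seed=0)
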