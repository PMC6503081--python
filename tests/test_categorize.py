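"""Categorization: candidate ordering, licensing, re-representation."""

import itertools

import numpy as np
import pytest

from chunklearn import (BigramModel, RunConfig, apply_merge,
                        best_licensed_merge, candidate_merges,
                        license_and_apply_merge, license_merge,
                        memory_from_symbols, merge_delta_hbar)


class TestCandidates:
    def test_shared_predecessor_pair_ranks_first(self, toy_ids):
        model = BigramModel.from_sequence(toy_ids)
        cands = candidate_merges(model, toy_ids)
        assert cands[0].pair == ("d", "e")  # only shared-predecessor pair
        assert cands[0].priority == pytest.approx(1.0)

    def test_single_symbol_alphabet_yields_nothing(self):
        ids = list("aaa")
        assert candidate_merges(BigramModel.from_sequence(ids), ids) == []

    def test_ordering_is_deterministic(self, toy_ids):
        model = BigramModel.from_sequence(toy_ids)
        assert candidate_merges(model, toy_ids) == candidate_merges(model, toy_ids)

    def test_remaining_pairs_involve_the_newest_symbol(self, toy_ids):
        model = BigramModel.from_sequence(toy_ids)
        cands = candidate_merges(model, toy_ids)
        for c in cands[1:]:
            assert "e" in c.pair  # e is the newest symbol


class TestLicensing:
    def test_toy_merge_drives_hbar_to_zero(self, toy_memory):
        """Merging the two branch symbols removes all uncertainty."""
        model = BigramModel.from_sequence(list("abdabe"))
        cand = candidate_merges(model, list("abdabe"))[0]
        decision = license_and_apply_merge(toy_memory, 0, cand)
        assert decision.accepted
        assert decision.delta_hbar == pytest.approx(-1 / 3)
        assert toy_memory.total_mean_ic() == 0.0

    def test_branch_creating_merge_is_rejected(self, toy_memory):
        """Merging an early arbitrary pair introduces new uncertainty and is
        rejected because h-bar would increase."""
        delta = merge_delta_hbar(list("abdabe"), ("a", "b"))
        assert delta == pytest.approx(2 / 3)
        model = BigramModel.from_sequence(list("abdabe"))
        cand = [c for c in candidate_merges(model, list("abdabe"))
                if set(c.pair) == {"a", "e"}][0]
        decision = license_merge(toy_memory, 0, cand)
        assert not decision.accepted

    def test_convexity_veto_blocks_an_hbar_reducing_merge(self):
        """Geometric mode: an outsider between the members vetoes the merge
        even though h-bar would fall."""
        cfg = RunConfig(space_mode="custom", rho=0.0)
        mem = memory_from_symbols("abdabe", cfg)
        mem.points[0] = {"a": [0.0], "b": [10.0], "d": [1.0], "e": [2.0],
                         }
        mem.points[0]["c_out"] = [1.5]  # lies between d and e
        mem.layers[mem.base_key].alphabet.add("c_out")
        model = BigramModel.from_sequence(list("abdabe"))
        cand = candidate_merges(model, list("abdabe"))[0]
        assert cand.pair == ("d", "e")
        decision = license_merge(mem, 0, cand)
        assert decision.delta_hbar < 0
        assert not decision.convexity_ok
        assert not decision.accepted

    def test_stale_candidate_is_signalled(self, toy_memory):
        model = BigramModel.from_sequence(list("abdabe"))
        cand = candidate_merges(model, list("abdabe"))[0]
        apply_merge(toy_memory, 0, cand.pair)
        decision = license_merge(toy_memory, 0, cand)
        assert not decision.accepted
        assert decision.reason == "stale candidate"

    def test_equality_mode_never_licenses_distinct_symbols(self, toy_ids):
        mem = memory_from_symbols("abdabe", RunConfig(space_mode="equality"))
        assert best_licensed_merge(mem, 0) is None


class TestReRepresentation:
    def test_merge_generalizes_continuations(self):
        """After merging s1 and s2, a continuation seen only after s1 gains
        probability in s2's contexts: a new expectation is created."""
        ids = list("abdxabe")  # x follows d, never e
        mem = memory_from_symbols("abdxabe", RunConfig(space_mode="indicator"))
        before = BigramModel.from_sequence(ids)
        assert before.prob("e", "x") in (None, 0.0)
        apply_merge(mem, 0, ("d", "e"))
        merged = mem.effective_layer(0).sequence()
        after = BigramModel.from_sequence(merged)
        assert after.prob("{d|e}", "x") > 0.0

    def test_merging_preserves_the_literal_record(self, toy_memory):
        apply_merge(toy_memory, 0, ("d", "e"))
        assert toy_memory.layers[toy_memory.base_key].sequence() == list("abdabe")
        assert toy_memory.layer_ground(toy_memory.effective_key(0)) == "abdabe"

    def test_chained_merges_compress_into_one_layer(self, toy_memory):
        apply_merge(toy_memory, 0, ("d", "e"))
        apply_merge(toy_memory, 0, ("a", "{d|e}"))
        assert len(toy_memory.stages) == 1
        cat_key = toy_memory.stages[0].cat
        assert toy_memory.pi[cat_key]["{a|d|e}"] == ["a", "d", "e"]
        members = [m for ms in toy_memory.pi[cat_key].values() for m in ms]
        assert len(members) == len(set(members))  # partition stays disjoint

    def test_vacuous_collapse_reaches_zero_hbar_and_one_symbol(self):
        rng = np.random.default_rng(5)
        ids = [chr(97 + int(i)) for i in rng.integers(0, 4, 30)]
        mem = memory_from_symbols(ids, RunConfig(space_mode="indicator"))
        while len(mem.effective_layer(0).alphabet) > 1:
            al = sorted(mem.effective_layer(0).alphabet)
            apply_merge(mem, 0, (al[0], al[1]))
        assert mem.total_mean_ic() == 0.0
        assert len(mem.effective_layer(0).alphabet) == 1


class TestOracleEquivalence:
    def test_greedy_merge_matches_exhaustive_search(self):
        """The accepted merge achieves the best single-merge h-bar reduction
        found by brute force over all symbol pairs."""
        rng = np.random.default_rng(42)
        cfg = RunConfig(space_mode="indicator")
        for _ in range(60):
            k = int(rng.integers(2, 7))
            L = int(rng.integers(2, 16))
            ids = [chr(97 + int(x)) for x in rng.integers(0, k, L)]
            mem = memory_from_symbols(ids, cfg)
            best = best_licensed_merge(mem, 0)
            deltas = [merge_delta_hbar(ids, p)
                      for p in itertools.combinations(sorted(set(ids)), 2)]
            optimum = min(deltas, default=0.0)
            if best is None:
                assert optimum >= -1e-9
            else:
                assert abs(best.delta_hbar - optimum) <= 1e-9
                assert best.delta_hbar < 0
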