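"""Discover a negation prefix by off-line re-segmentation.

Phase 1 exposes the learner to five adjectives and their fused negated
forms ("in"+adjective): ten content forms are stored whole.  Phase 2 then
supplies evidence of the free-standing prefix.  Consolidation re-evaluates
boundary flags inside the stored chunks and splits each fused form at the
prefix edge, shrinking the relevant lexicon from 2n = 10 symbols to
n + 1 = 6 — the learner has discovered "in" from its own data.
"""

from chunklearn import (ConsolidationBudget, consolidate, extend,
                        generate_prefix_scenario, learn)

n = 5
scen = generate_prefix_scenario(n, seed=1)
relevant = set(scen.fused_forms) | set(scen.adjectives) | {scen.prefix}


def relevant_lexicon(memory):
    lex_key = memory.stages[1].base
    contents = {"".join(memory.lam[lex_key][s])
                for s in memory.layers[lex_key].alphabet}
    return sorted(contents & relevant)


memory = learn(scen.phase1_text)
before = relevant_lexicon(memory)
print(f"after fused exposure ({len(scen.phase1_tokens)} tokens), "
      f"{len(before)} relevant lexical symbols:\n  {before}")

extend(memory, scen.phase2_text)
out, log = consolidate(memory, ConsolidationBudget(40))

print(f"\nconsolidation applied {len(log)} operations:")
for rec in log.records:
    print(f"  {rec.op:12s} {rec.detail:14s} "
          f"sum h-bar {rec.sum_hbar_before:.4f} -> {rec.sum_hbar_after:.4f}")

after = relevant_lexicon(out)
print(f"\nafter consolidation, {len(after)} relevant lexical symbols:\n  {after}")
print(f"\nlexicon economy: 2n = {2 * n} fused/bare forms became "
      f"n + 1 = {n + 1} (prefix + bare adjectives).")
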