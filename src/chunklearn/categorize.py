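"""Information-efficiency-licensed categorization (the Pi relation).

Pairs of symbols that share a predecessor are candidate concepts; a merge is
licensed by a strict decrease of the layer's mean information content h-bar
and by the convexity gate of an available semantic space.  Merges are applied
as a re-representation into a categorization layer rather than a destructive
rewrite, so the literal record is preserved; chained merges are compressed
into the single categorization layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .bigram import BigramModel, mean_ic
from .memory import Memory, Symbol, append_moment
from .spaces import ConvexityParams, SemanticSpace, convexity_gate, indicator_space

TOL = 1e-9


@dataclass(frozen=True)
class MergeCandidate:
    pair: tuple[str, str]
    priority: float  # max moment-wise h over the pair's occurrences, bits
    first_tau: int   # earliest occurrence of either member


@dataclass(frozen=True)
class MergeDecision:
    pair: tuple[str, str]
    accepted: bool
    delta_hbar: float
    convexity_ok: bool
    space_used: Optional[str]
    reason: str = ""


def candidate_merges(model: BigramModel, ids: list[str]) -> list[MergeCandidate]:
    """Ordered merge candidates for a layer sequence.

    Shared-predecessor pairs come first, ordered by decreasing maximum
    moment-wise h over either member's occurrences, ties broken by earliest
    occurrence; pairs involving the newest symbol (the one whose first
    occurrence is latest) are appended afterwards in the same order.
    """
    symbols = sorted(set(ids))
    if len(symbols) < 2:
        return []
    h = model.h_profile(ids)
    first: dict[str, int] = {}
    max_h: dict[str, float] = {}
    for t, s in enumerate(ids):
        first.setdefault(s, t)
        if h[t] is not None:
            max_h[s] = max(max_h.get(s, 0.0), h[t])
    preds: dict[str, set[str]] = {s: set() for s in symbols}
    for pred, succs in model.counts.items():
        for succ in succs:
            if succ in preds:
                preds[succ].add(pred)

    def key(pair: tuple[str, str]):
        prio = max(max_h.get(pair[0], 0.0), max_h.get(pair[1], 0.0))
        tau = min(first[pair[0]], first[pair[1]])
        return (-prio, tau, pair)

    shared, rest = [], []
    for i, s1 in enumerate(symbols):
        for s2 in symbols[i + 1:]:
            (shared if preds[s1] & preds[s2] else rest).append((s1, s2))
    newest = max(symbols, key=lambda s: first[s])
    rest = [p for p in rest if newest in p]
    out = sorted(shared, key=key) + sorted(rest, key=key)
    return [
        MergeCandidate(pair=p,
                       priority=max(max_h.get(p[0], 0.0), max_h.get(p[1], 0.0)),
                       first_tau=min(first[p[0]], first[p[1]]))
        for p in out
    ]


def category_id(members: list[str]) -> str:
    return "{" + "|".join(sorted(members)) + "}"


def _expanded_members(memory: Memory, stage_index: int, sym: str) -> list[str]:
    """Subordinate-layer member ids of an effective symbol (itself if atomic)."""
    st = memory.stages[stage_index]
    if st.cat is not None:
        return list(memory.pi[st.cat].get(sym, [sym]))
    return [sym]


def merged_sequence(ids: list[str], pair: tuple[str, str], cid: str) -> list[str]:
    return [cid if s in pair else s for s in ids]


def merge_delta_hbar(ids: list[str], pair: tuple[str, str]) -> float:
    """Change in the layer's h-bar if the pair were merged (static counts)."""
    cid = category_id(list(pair))
    return mean_ic(merged_sequence(ids, pair, cid))[0] - mean_ic(ids)[0]


def space_for_stage(memory: Memory, stage_index: int) -> Optional[SemanticSpace]:
    """The semantic space used to gate merges on a stage's effective layer.

    equality mode -> None (the gate degenerates to exact identity and no
    distinct pair is ever licensed); indicator mode -> orthonormal indicator
    points over the effective alphabet; custom mode -> user points for the
    stage's base symbols, categories placed at member centroids.
    """
    mode = memory.config.space_mode
    if mode == "equality":
        return None
    eff = memory.effective_layer(stage_index)
    alphabet = sorted(eff.alphabet)
    if mode == "indicator":
        return indicator_space(alphabet, inner_product=memory.config.inner_product)
    base_points = memory.points.get(stage_index)
    if base_points is None:
        raise ValueError(f"custom space mode but no points for stage {stage_index}")
    helper = SemanticSpace(base_points, inner_product=memory.config.inner_product)
    pts = {
        s: helper.centroid(_expanded_members(memory, stage_index, s))
        for s in alphabet
    }
    return SemanticSpace(pts, inner_product=memory.config.inner_product)


def apply_merge(memory: Memory, stage_index: int, pair: tuple[str, str]) -> str:
    """Re-represent a stage under the merge of two effective symbols.

    Creates the stage's categorization layer on first use (every symbol gets
    a Pi entry; unmerged symbols are singleton categories keeping their id)
    and compresses chained merges into it.  Returns the category id.
    """
    st = memory.stages[stage_index]
    eff_key = memory.effective_key(stage_index)
    eff = memory.layers[eff_key]
    s1, s2 = pair
    if s1 not in eff.alphabet or s2 not in eff.alphabet:
        raise KeyError(f"stale candidate {pair}: not in the effective alphabet")
    members = sorted(_expanded_members(memory, stage_index, s1)
                     + _expanded_members(memory, stage_index, s2))
    cid = category_id(members)
    if st.cat is None:
        base = memory.layers[st.base]
        layer = memory.new_layer("category", alpha=base.alpha + 1, source=st.base)
        mapping = {s: (cid if s in pair else s) for s in base.alphabet}
        for m in base.moments:
            append_moment(layer, Symbol(mapping[m.symbol_id], layer.delta, layer.alpha),
                          m.span)
        memory.pi[layer.key] = {cid: members}
        for s in sorted(base.alphabet):
            if s not in pair:
                memory.pi[layer.key][s] = [s]
        st.cat = layer.key
    else:
        layer = memory.layers[st.cat]
        pi = memory.pi[st.cat]
        for m in layer.moments:
            if m.symbol_id in pair:
                m.symbol_id = cid
        for s in pair:
            pi.pop(s, None)
        pi[cid] = members
        layer.alphabet = {m.symbol_id for m in layer.moments}
    return cid


def license_merge(memory: Memory, stage_index: int,
                  candidate: MergeCandidate,
                  params: Optional[ConvexityParams] = None) -> MergeDecision:
    """Evaluate (without applying) the licensing of one merge candidate."""
    params = params or ConvexityParams(rho=memory.config.rho)
    eff = memory.effective_layer(stage_index)
    ids = eff.sequence()
    for s in candidate.pair:
        if s not in eff.alphabet:
            return MergeDecision(candidate.pair, False, 0.0, False, None,
                                 reason="stale candidate")
    delta = merge_delta_hbar(ids, candidate.pair)
    space = space_for_stage(memory, stage_index)
    if space is None:
        convex_ok = candidate.pair[0] == candidate.pair[1]  # identity gate
        space_used = None
    else:
        convex_ok = convexity_gate(space, list(candidate.pair), params)
        space_used = space.inner_product
    accepted = bool(delta < -TOL and convex_ok)
    reason = "" if accepted else (
        "h-bar would not strictly decrease" if delta >= -TOL else "convexity veto"
    )
    return MergeDecision(candidate.pair, accepted, delta, convex_ok, space_used,
                         reason)


def license_and_apply_merge(memory: Memory, stage_index: int,
                            candidate: MergeCandidate,
                            params: Optional[ConvexityParams] = None
                            ) -> MergeDecision:
    """License one candidate and, when accepted, apply it to the memory."""
    decision = license_merge(memory, stage_index, candidate, params)
    if decision.accepted:
        apply_merge(memory, stage_index, candidate.pair)
    return decision


def best_licensed_merge(memory: Memory, stage_index: int,
                        params: Optional[ConvexityParams] = None
                        ) -> Optional[MergeDecision]:
    """The licensed candidate with the largest h-bar reduction, or None.

    Candidates are generated by `candidate_merges`; ties fall to the
    heuristic order.  Shared-predecessor pairs dominate all others, so the
    winner matches an exhaustive search over symbol pairs.
    """
    eff = memory.effective_layer(stage_index)
    ids = eff.sequence()
    model = BigramModel.from_sequence(ids)
    best: Optional[MergeDecision] = None
    for cand in candidate_merges(model, ids):
        d = license_merge(memory, stage_index, cand, params)
        if d.accepted and (best is None or d.delta_hbar < best.delta_hbar - TOL):
            best = d
    return best


def greedy_categorize(memory: Memory, stage_index: int,
                      params: Optional[ConvexityParams] = None
                      ) -> list[MergeDecision]:
    """Apply best licensed merges until none remains; returns the decisions."""
    applied: list[MergeDecision] = []
    while True:
        best = best_licensed_merge(memory, stage_index, params)
        if best is None:
            return applied
        apply_merge(memory, stage_index, best.pair)
        applied.append(best)
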