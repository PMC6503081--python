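"""Off-line consolidation: re-represent the memory toward minimal total mean
information content.

The loop takes the symbol with the highest information content, attempts to
categorize it with others, then attempts to (re-)segment around it; on
success it restarts from the new highest-h symbol, otherwise it moves to the
next highest, until nothing applies or the iteration budget is exhausted.
Four operations are available: categorization, segmentation (boundary
revision), re-categorization (splitting a category) and re-segmentation
(splitting a chunk).  Every accepted operation is licensed on a trial copy
after the change has rippled upward through rebuilt superordinate layers:
total h-bar must not increase (strictly decrease for the categorization
operations).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

from .bigram import BigramModel
from .categorize import (TOL, candidate_merges, category_id, apply_merge,
                         license_merge)
from .chunker import boundary_flags, chunk_id
from .hierarchy import grow
from .memory import Memory, Moment, Symbol


@dataclass(frozen=True)
class ConsolidationBudget:
    """max_iterations bounds accepted operations (a deterministic proxy for
    the time available off-line); seed is recorded for provenance."""

    max_iterations: int
    seed: int = 0

    def __post_init__(self):
        if self.max_iterations < 0:
            raise ValueError("budget must be non-negative")


@dataclass(frozen=True)
class OperationRecord:
    op: str                 # categorize | re-categorize | re-segment
    stage: int
    detail: str
    sum_hbar_before: float
    sum_hbar_after: float


@dataclass
class OperationLog:
    records: list[OperationRecord] = field(default_factory=list)

    def append(self, rec: OperationRecord) -> None:
        if rec.sum_hbar_after > rec.sum_hbar_before + TOL:
            raise AssertionError("accepted operation increased total h-bar")
        self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)


# -- structural mutators (no licensing; callers license on a trial copy) ----

def _drop_stages_above(memory: Memory, stage_index: int) -> None:
    for st in memory.stages[stage_index + 1:]:
        for key in (st.base, st.cat):
            if key is not None:
                memory.layers.pop(key, None)
                memory.lam.pop(key, None)
                memory.pi.pop(key, None)
    del memory.stages[stage_index + 1:]


def _rebuild_above(memory: Memory, stage_index: int) -> None:
    _drop_stages_above(memory, stage_index)
    grow(memory)


def _chunk_cuts(memory: Memory, stage_index: int, chunk_sym: str) -> list[int]:
    """Interior split positions of a chunk where boundary flags fire under
    the current model of its source layer (within-chunk context only)."""
    key = memory.stages[stage_index].base
    layer = memory.layers[key]
    if layer.kind != "chunk" or chunk_sym not in memory.lam.get(key, {}):
        return []
    content = memory.lam[key][chunk_sym]
    if len(content) < 2:
        return []
    src = memory.layers[layer.source]
    model = BigramModel.from_sequence(src.sequence())
    h = [None] + [model.information_content(content[j - 1], content[j])
                  for j in range(1, len(content))]
    H = [model.entropy(s) for s in content]
    flags = boundary_flags(h, H, memory.config.detector)
    cuts = set()
    for t, f in enumerate(flags):
        if f:
            cut = t if memory.config.boundary_shift else t + 1
            if 0 < cut < len(content):
                cuts.add(cut)
    return sorted(cuts)


def _split_chunk(memory: Memory, stage_index: int, chunk_sym: str) -> bool:
    """Re-evaluate boundary flags inside a chunk under the current model of
    its source layer and split it wherever they fire.  Returns whether the
    structure changed (superordinate layers are rebuilt)."""
    cuts = _chunk_cuts(memory, stage_index, chunk_sym)
    if not cuts:
        return False
    key = memory.stages[stage_index].base
    layer = memory.layers[key]
    src = memory.layers[layer.source]
    content = memory.lam[key][chunk_sym]
    bounds = [0] + cuts + [len(content)]
    parts = [content[bounds[i]:bounds[i + 1]] for i in range(len(bounds) - 1)]

    # stale categorization of the chunk layer cannot survive a re-partition
    st = memory.stages[stage_index]
    if st.cat is not None:
        memory.layers.pop(st.cat, None)
        memory.pi.pop(st.cat, None)
        st.cat = None

    lam = memory.lam[key]
    new_moments: list[Moment] = []
    for tau, m in enumerate(layer.moments):
        if m.symbol_id != chunk_sym:
            new_moments.append(m)
            continue
        lo, _hi = memory.subordinate_range(key, tau)
        pos = 0
        for part in parts:
            cid = chunk_id(part)
            lam.setdefault(cid, part)
            span = (src.moments[lo + pos].start,
                    src.moments[lo + pos + len(part) - 1].end)
            new_moments.append(Moment(tau=0, symbol_id=cid,
                                      start=span[0], end=span[1]))
            pos += len(part)
    for i, m in enumerate(new_moments):
        m.tau = i
    layer.moments = new_moments
    layer.alphabet = {m.symbol_id for m in new_moments}
    del lam[chunk_sym]
    _rebuild_above(memory, stage_index)
    return True


def _split_category(memory: Memory, stage_index: int, cat_sym: str) -> bool:
    """Propose a 2-way split of a category by successor-distribution
    divergence of its members and apply it (superordinate layers rebuilt)."""
    st = memory.stages[stage_index]
    if st.cat is None:
        return False
    members = memory.pi[st.cat].get(cat_sym, [])
    if len(members) < 2:
        return False
    base = memory.layers[st.base]
    model = BigramModel.from_sequence(base.sequence())

    def dist(s: str) -> dict[str, float]:
        return model.distribution(s) or {}

    def tv(a: dict, b: dict) -> float:
        keys = set(a) | set(b)
        return 0.5 * sum(abs(a.get(k, 0.0) - b.get(k, 0.0)) for k in keys)

    dists = {s: dist(s) for s in members}
    seeds = max(((a, b) for i, a in enumerate(members) for b in members[i + 1:]),
                key=lambda p: (tv(dists[p[0]], dists[p[1]]), p))
    g1, g2 = [seeds[0]], [seeds[1]]
    for s in members:
        if s in seeds:
            continue
        (g1 if tv(dists[s], dists[seeds[0]]) <= tv(dists[s], dists[seeds[1]])
         else g2).append(s)
    id1 = category_id(g1) if len(g1) > 1 else g1[0]
    id2 = category_id(g2) if len(g2) > 1 else g2[0]
    lookup = {s: id1 for s in g1}
    lookup.update({s: id2 for s in g2})

    cat_layer = memory.layers[st.cat]
    for tau, m in enumerate(cat_layer.moments):
        if m.symbol_id == cat_sym:
            m.symbol_id = lookup[base.moments[tau].symbol_id]
    pi = memory.pi[st.cat]
    del pi[cat_sym]
    pi[id1] = sorted(g1)
    pi[id2] = sorted(g2)
    cat_layer.alphabet = {m.symbol_id for m in cat_layer.moments}
    _rebuild_above(memory, stage_index)
    return True


# -- licensed attempts ------------------------------------------------------

def _adopt(memory: Memory, trial: Memory) -> None:
    memory.__dict__.update(trial.__dict__)


def _attempt(memory: Memory, mutator, strict: bool) -> Optional[tuple[float, float]]:
    """Run a mutator on a trial copy; adopt it iff total h-bar is licensed.
    Returns (before, after) when adopted, else None."""
    before = memory.total_mean_ic()
    trial = copy.deepcopy(memory)
    if not mutator(trial):
        return None
    after = trial.total_mean_ic()
    ok = after < before - TOL if strict else after <= before + TOL
    if not ok:
        return None
    _adopt(memory, trial)
    return before, after


def _try_categorize(memory: Memory, stage_index: int, sym: str
                    ) -> Optional[OperationRecord]:
    eff = memory.effective_layer(stage_index)
    ids = eff.sequence()
    model = BigramModel.from_sequence(ids)
    best = None
    for cand in candidate_merges(model, ids):
        if sym not in cand.pair:
            continue
        d = license_merge(memory, stage_index, cand)
        if d.accepted and (best is None or d.delta_hbar < best.delta_hbar - TOL):
            best = d
    if best is None:
        return None

    def mutate(trial: Memory) -> bool:
        apply_merge(trial, stage_index, best.pair)
        _rebuild_above(trial, stage_index)
        return True

    res = _attempt(memory, mutate, strict=True)
    if res is None:
        return None
    return OperationRecord("categorize", stage_index, "+".join(best.pair), *res)


def _try_split_category(memory: Memory, stage_index: int, sym: str
                        ) -> Optional[OperationRecord]:
    res = _attempt(memory, lambda t: _split_category(t, stage_index, sym),
                   strict=True)
    if res is None:
        return None
    return OperationRecord("re-categorize", stage_index, sym, *res)


def _try_resegment(memory: Memory, stage_index: int, sym: str
                   ) -> Optional[OperationRecord]:
    targets: list[tuple[int, str]] = []
    st = memory.stages[stage_index]
    if st.cat is None and memory.layers[st.base].kind == "chunk":
        if sym in memory.lam.get(st.base, {}):
            targets.append((stage_index, sym))
    if stage_index + 1 < len(memory.stages):
        up_key = memory.stages[stage_index + 1].base
        up = memory.layers[up_key]
        seen = set()
        for m in up.moments:  # chunks containing sym, in order of appearance
            if m.symbol_id in seen:
                continue
            seen.add(m.symbol_id)
            content = memory.lam.get(up_key, {}).get(m.symbol_id, ())
            if sym in content:
                targets.append((stage_index + 1, m.symbol_id))
    for si, chunk_sym in targets:
        if not _chunk_cuts(memory, stage_index=si, chunk_sym=chunk_sym):
            continue  # no interior flag fires; skip the trial copy
        res = _attempt(memory, lambda t, si=si, c=chunk_sym: _split_chunk(t, si, c),
                       strict=False)
        if res is not None:
            return OperationRecord("re-segment", si, chunk_sym, *res)
    return None


def apply_split(memory: Memory, target: str, kind: str) -> bool:
    """Licensed split of a category ("re-categorize") or chunk ("re-segment").

    The target symbol is looked up across stages; returns whether a licensed
    change was applied (False for singleton categories / length-1 chunks or
    when the total h-bar licensing fails)."""
    if kind == "re-categorize":
        for i, st in enumerate(memory.stages):
            if st.cat is not None and target in memory.pi.get(st.cat, {}):
                return _try_split_category(memory, i, target) is not None
        return False
    if kind == "re-segment":
        for i, st in enumerate(memory.stages):
            if target in memory.lam.get(st.base, {}):
                res = _attempt(memory, lambda t, i=i: _split_chunk(t, i, target),
                               strict=False)
                return res is not None
        return False
    raise ValueError(f"unknown split kind {kind!r}")


# -- the consolidation loop --------------------------------------------------

def attention_order(memory: Memory) -> list[tuple[float, int, int, int, str]]:
    """Symbols of all active layers ranked by decreasing information content
    (a symbol scores its highest-h moment); ties break by lower level, then
    earlier occurrence.  Returns (h, alpha, first_tau, stage, symbol) tuples."""
    entries: dict[tuple[int, str], list] = {}
    for i in range(len(memory.stages)):
        layer = memory.effective_layer(i)
        ids = layer.sequence()
        model = BigramModel.from_sequence(ids)
        profile = model.h_profile(ids)
        for tau, s in enumerate(ids):
            hval = profile[tau]
            if hval is None:
                continue
            key = (i, s)
            if key not in entries:
                entries[key] = [hval, layer.alpha, tau, i, s]
            else:
                entries[key][0] = max(entries[key][0], hval)
    out = [tuple(v) for v in entries.values()]
    out.sort(key=lambda e: (-e[0], e[1], e[2], e[4]))
    return out


def consolidate(memory: Memory, budget: ConsolidationBudget
                ) -> tuple[Memory, OperationLog]:
    """Run the consolidation loop within an iteration budget.

    The input memory is left untouched; the revised memory and the log of
    accepted operations (with total h-bar before/after each) are returned.
    Deterministic for a given memory and budget."""
    mem = copy.deepcopy(memory)
    log = OperationLog()
    for _ in range(budget.max_iterations):
        applied = None
        for hval, _alpha, _tau, stage_index, sym in attention_order(mem):
            applied = (_try_categorize(mem, stage_index, sym)
                       or _try_split_category(mem, stage_index, sym)
                       or _try_resegment(mem, stage_index, sym))
            if applied is not None:
                log.append(applied)
                break
        if applied is None:
            break
    return mem, log
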