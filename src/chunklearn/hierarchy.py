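"""Hierarchy construction: stack chunk (and, in geometric modes,
categorization) layers until no further re-representation is possible."""

from __future__ import annotations

from typing import Optional

from .categorize import greedy_categorize
from .chunker import boundary_flags, chunk_id, profiles_for, segment_layer
from .config import RunConfig
from .memory import Memory, Symbol, append_moment, memory_from_symbols


def grow(memory: Memory, config: Optional[RunConfig] = None) -> None:
    """Interleave categorization and segmentation upward from the top stage
    until a fixpoint (no compression) or the level cap is reached."""
    config = config or memory.config
    while len(memory.stages) < config.max_levels:
        i = len(memory.stages) - 1
        if config.space_mode != "equality":
            greedy_categorize(memory, i)
        if segment_layer(memory, i, config) is None:
            break


def learn(text: str, config: Optional[RunConfig] = None) -> Memory:
    """Build a full hierarchical memory over a symbol stream (one character
    per base-level moment)."""
    if not text:
        raise ValueError("empty input stream")
    memory = memory_from_symbols(text, config)
    grow(memory, memory.config)
    return memory


def extend(memory: Memory, text: str) -> None:
    """Append new input to an existing memory (continued waking exposure).

    The base layer grows; the first chunk layer is extended by segmenting the
    appended region only (with a forced boundary at the junction, under the
    model of the now-complete layer), so chunks committed earlier stay as
    they were stored — later revision is consolidation's job.  Stages above
    the first chunk layer are rebuilt.
    """
    if not text:
        return
    config = memory.config
    base = memory.layers[memory.stages[0].base]
    if memory.stages[0].cat is not None:
        raise ValueError("cannot extend a memory whose base layer was re-represented")
    old_len = len(base)
    for i, ch in enumerate(text):
        append_moment(base, Symbol(ch, base.delta, base.alpha),
                      (old_len + i, old_len + i + 1))

    if len(memory.stages) == 1:
        grow(memory, config)
        return

    # drop stages above the first chunk layer; they are rebuilt below
    for st in memory.stages[2:]:
        for key in (st.base, st.cat):
            if key is not None:
                memory.layers.pop(key, None)
                memory.lam.pop(key, None)
                memory.pi.pop(key, None)
    del memory.stages[2:]

    chunk_key = memory.stages[1].base
    layer = memory.layers[chunk_key]
    lam = memory.lam.setdefault(chunk_key, {})
    ids = base.sequence()
    h, H = profiles_for(ids, config)
    flags = boundary_flags(h, H, config.detector)
    # segment only the appended region; the junction is a forced boundary
    cuts = []
    for t in range(old_len, len(ids)):
        if flags[t]:
            cut = t if config.boundary_shift else t + 1
            if old_len < cut < len(ids):
                cuts.append(cut)
    bounds = [old_len] + sorted(set(cuts)) + [len(ids)]
    for j in range(len(bounds) - 1):
        lo, hi = bounds[j], bounds[j + 1]
        content = tuple(ids[lo:hi])
        cid = chunk_id(content)
        lam.setdefault(cid, content)
        append_moment(layer, Symbol(cid, layer.delta, layer.alpha), (lo, hi))
    grow(memory, config)
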