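"""Boundary detection by information dynamics and chunk-layer construction.

A boundary detector turns the moment-wise h / H profiles of a layer into
Boolean flags; segments are promoted to superordinate chunk symbols whose
identity (in the default equality mode) is the subtended content itself, and
the subtend relation Lambda records the mapping.
"""

from __future__ import annotations

from typing import Optional

from .bigram import BigramModel, online_profiles, static_profiles
from .config import ConfigError, RunConfig
from .memory import Memory, Stage, Symbol, append_moment


def _lt(a: Optional[float], b: Optional[float]) -> bool:
    return a is not None and b is not None and a < b


def _ge(a: Optional[float], b: Optional[float]) -> bool:
    return a is not None and b is not None and a >= b


def boundary_flags(h: list[Optional[float]], H: list[Optional[float]],
                   detector: str) -> list[bool]:
    """Per-moment Boolean flags from the printed detector definitions.

    simple:  flag at tau iff h(tau) < h(tau+1).
    complex: flag at tau if H(tau-1) < H(tau); else if H(tau-1) >= H(tau)
             and h(tau) < h(tau+1); else no flag.
    Whenever a referenced value is undefined (a sequence edge or an unseen
    context), no boundary is asserted at that clause.
    """
    n = len(h)
    flags = [False] * n
    for t in range(n):
        if detector == "simple":
            flags[t] = t + 1 < n and _lt(h[t], h[t + 1])
        elif detector == "complex":
            if t >= 1 and _lt(H[t - 1], H[t]):
                flags[t] = True
            elif t >= 1 and _ge(H[t - 1], H[t]) and t + 1 < n and _lt(h[t], h[t + 1]):
                flags[t] = True
        else:
            raise ConfigError(f"unknown detector {detector!r}")
    return flags


def detect_boundary(model: BigramModel, ids: list[str], tau: int,
                    detector: str) -> bool:
    """The flag at one moment of a sequence under a given (static) model."""
    if not 0 <= tau < len(ids):
        raise IndexError(tau)
    h = model.h_profile(ids)
    H = model.entropy_profile(ids)
    return boundary_flags(h, H, detector)[tau]


def profiles_for(ids: list[str], config: RunConfig
                 ) -> tuple[list[Optional[float]], list[Optional[float]]]:
    if config.mode == "online":
        return online_profiles(ids, smoothing=config.smoothing)
    return static_profiles(ids)


def segments_from_flags(n: int, flags: list[bool], shift: bool = False
                        ) -> list[tuple[int, int]]:
    """Half-open [lo, hi) moment-index ranges tiling 0..n.

    shift=False: a true flag at tau closes the current segment after tau.
    shift=True:  a true flag at tau starts a new segment at tau (the literal
    reading of "tau is the first moment in a new segment").
    """
    cuts = set()
    for t in range(n):
        if flags[t]:
            if shift:
                if t >= 1:
                    cuts.add(t)
            else:
                if t + 1 < n:
                    cuts.add(t + 1)
    bounds = [0] + sorted(cuts) + [n]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def chunk_id(content: tuple[str, ...]) -> str:
    """Identity-by-content name for a chunk symbol."""
    return "(" + " ".join(content) + ")"


def segment_layer(memory: Memory, stage_index: int,
                  config: Optional[RunConfig] = None) -> Optional[tuple[int, int]]:
    """Segment a stage's effective layer into a new superordinate chunk layer.

    Returns the new layer's key, or None when segmentation would not compress
    (every segment a single moment, or the layer has a single moment).
    Each distinct subtended content maps to one chunk symbol, recorded in
    Lambda; chunk spans concatenate the subtended spans.
    """
    config = config or memory.config
    src_key = memory.effective_key(stage_index)
    src = memory.layers[src_key]
    ids = src.sequence()
    if not ids:
        raise ValueError("cannot segment an empty layer")
    h, H = profiles_for(ids, config)
    flags = boundary_flags(h, H, config.detector)
    segs = segments_from_flags(len(ids), flags, shift=config.boundary_shift)
    if len(segs) >= len(ids):
        return None
    layer = memory.new_layer("chunk", alpha=src.alpha + 1, source=src_key)
    lam = memory.lam.setdefault(layer.key, {})
    for lo, hi in segs:
        content = tuple(ids[lo:hi])
        cid = chunk_id(content)
        lam.setdefault(cid, content)
        span = (src.moments[lo].start, src.moments[hi - 1].end)
        append_moment(layer, Symbol(cid, layer.delta, layer.alpha), span)
    memory.stages.append(Stage(base=layer.key))
    return layer.key


def layer_profile(memory: Memory, stage_index: int,
                  config: Optional[RunConfig] = None) -> list[dict]:
    """Per-moment (tau, symbol, H, h, flag) records for inspection/dumps."""
    config = config or memory.config
    layer = memory.effective_layer(stage_index)
    ids = layer.sequence()
    h, H = profiles_for(ids, config)
    flags = boundary_flags(h, H, config.detector)
    return [
        {"tau": t, "symbol": ids[t], "H": H[t], "h": h[t], "flag": flags[t]}
        for t in range(len(ids))
    ]
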