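"""Layered sequential memory.

The memory keeps a literal record of its input at level 0 and stacks
re-representations above it: *chunk* layers created by segmentation (each
moment subtends a contiguous run of subordinate moments, the Lambda relation)
and *categorization* layers created by merging alphabet symbols into concepts
(the Pi relation, one moment per subordinate moment).  Every moment carries a
half-open span of base-level offsets, so any symbol can be traced back to the
raw input.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field
from typing import Iterator, Optional

from .config import RunConfig

SENTINEL = "^"

SCHEMA_VERSION = 1


class ContiguityError(ValueError):
    """A moment's span does not start where the previous one ended."""


class AlphabetError(ValueError):
    """A symbol was used outside its (delta, alpha) alphabet."""


class IntegrityError(ValueError):
    """A subtend / partition link is dangling or inconsistent."""


@dataclass(frozen=True)
class Symbol:
    """A symbol of one alphabet; identity is (id, delta, alpha)."""

    id: str
    delta: int
    alpha: int


@dataclass
class Moment:
    """One discrete time step of a layer: a symbol occurrence with a span."""

    tau: int
    symbol_id: str
    start: int
    end: int

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class Layer:
    """A contiguous sequence of moments over one alphabet.

    kind is "base" (literal input), "chunk" (built by segmentation) or
    "category" (a 1:1 re-representation under a partition of the source
    alphabet).  source is the key of the subordinate layer, None for base.
    """

    delta: int
    alpha: int
    kind: str
    source: Optional[tuple[int, int]] = None
    moments: list[Moment] = field(default_factory=list)
    alphabet: set[str] = field(default_factory=set)

    @property
    def key(self) -> tuple[int, int]:
        return (self.delta, self.alpha)

    def sequence(self) -> list[str]:
        return [m.symbol_id for m in self.moments]

    def __len__(self) -> int:
        return len(self.moments)


def append_moment(layer: Layer, symbol: Symbol, span: tuple[int, int]) -> int:
    """Append a moment to a layer, returning its ordinal tau.

    The span must be non-empty and begin exactly where the previous moment
    ended (at 0 for an empty layer); the symbol's (delta, alpha) must match
    the layer's.
    """
    if (symbol.delta, symbol.alpha) != layer.key:
        raise AlphabetError(
            f"symbol {symbol.id!r} belongs to layer {(symbol.delta, symbol.alpha)}, "
            f"not {layer.key}"
        )
    start, end = span
    if end <= start:
        raise ContiguityError(f"empty or inverted span {span}")
    expected = layer.moments[-1].end if layer.moments else 0
    if start != expected:
        raise ContiguityError(f"span {span} does not start at {expected}")
    tau = len(layer.moments)
    layer.moments.append(Moment(tau=tau, symbol_id=symbol.id, start=start, end=end))
    layer.alphabet.add(symbol.id)
    return tau


@dataclass
class Stage:
    """One level of the hierarchy: a sequence layer plus its optional
    categorization layer (the compressed single-layer view of chained merges)."""

    base: tuple[int, int]
    cat: Optional[tuple[int, int]] = None


class Memory:
    """The whole layered record: layers keyed by (delta, alpha), the
    Pi (partition) and Lambda (subtend) relations, and the stage chain."""

    def __init__(self, config: Optional[RunConfig] = None):
        self.config = (config or RunConfig()).validate()
        self.layers: dict[tuple[int, int], Layer] = {}
        self.stages: list[Stage] = []
        # pi[cat_layer_key][category_id] -> sorted list of subordinate member ids
        self.pi: dict[tuple[int, int], dict[str, list[str]]] = {}
        # lam[chunk_layer_key][chunk_id] -> tuple of subordinate symbol ids
        self.lam: dict[tuple[int, int], dict[str, tuple[str, ...]]] = {}
        # optional user-supplied geometry: points for base symbols per stage
        self.points: dict[int, dict[str, list[float]]] = {}
        self._next_delta = 0

    # -- construction -----------------------------------------------------

    def new_layer(self, kind: str, alpha: int, source: Optional[tuple[int, int]]) -> Layer:
        layer = Layer(delta=self._next_delta, alpha=alpha, kind=kind, source=source)
        self._next_delta += 1
        self.layers[layer.key] = layer
        return layer

    # -- views ------------------------------------------------------------

    @property
    def base_key(self) -> tuple[int, int]:
        return self.stages[0].base

    def base_text(self) -> str:
        return "".join(self.layers[self.base_key].sequence())

    def effective_key(self, stage_index: int) -> tuple[int, int]:
        """The key of the stage's active layer: its categorization layer if
        one exists (it supersedes the sequence it re-represents), else the
        stage's own sequence layer."""
        st = self.stages[stage_index]
        return st.cat if st.cat is not None else st.base

    def effective_layer(self, stage_index: int) -> Layer:
        return self.layers[self.effective_key(stage_index)]

    def active_keys(self) -> Iterator[tuple[int, int]]:
        for i in range(len(self.stages)):
            yield self.effective_key(i)

    def stage_of_key(self, key: tuple[int, int]) -> int:
        for i, st in enumerate(self.stages):
            if key in (st.base, st.cat):
                return i
        raise KeyError(key)

    # -- grounding --------------------------------------------------------

    def subordinate_range(self, key: tuple[int, int], tau: int) -> tuple[int, int]:
        """Indices [lo, hi) of the source-layer moments a chunk moment subtends."""
        layer = self.layers[key]
        m = layer.moments[tau]
        src = self.layers[layer.source]
        starts = [s.start for s in src.moments]
        lo = bisect.bisect_left(starts, m.start)
        hi = bisect.bisect_left(starts, m.end, lo)
        if lo >= hi or src.moments[lo].start != m.start or src.moments[hi - 1].end != m.end:
            raise IntegrityError(f"span {m.span} does not tile source layer {layer.source}")
        return lo, hi

    def trace_ground(self, key: tuple[int, int], tau: int) -> list[str]:
        """Base-level symbols covered by a moment, by recursive expansion
        through the Lambda / Pi links down to level 0."""
        layer = self.layers[key]
        m = layer.moments[tau]
        if layer.kind == "base":
            return [m.symbol_id]
        if layer.source not in self.layers:
            raise IntegrityError(f"layer {key} has dangling source {layer.source}")
        if layer.kind == "category":
            if key not in self.pi or m.symbol_id not in self.pi[key]:
                raise IntegrityError(f"dangling Pi link for {m.symbol_id!r} in {key}")
            return self.trace_ground(layer.source, tau)
        # chunk layer: expand through Lambda
        content = self.lam.get(key, {}).get(m.symbol_id)
        if content is None:
            raise IntegrityError(f"dangling Lambda link for {m.symbol_id!r} in {key}")
        lo, hi = self.subordinate_range(key, tau)
        src = self.layers[layer.source]
        if tuple(src.moments[j].symbol_id for j in range(lo, hi)) != content:
            raise IntegrityError(
                f"subtended content of {m.symbol_id!r} disagrees with Lambda"
            )
        out: list[str] = []
        for j in range(lo, hi):
            out.extend(self.trace_ground(layer.source, j))
        return out

    def layer_ground(self, key: tuple[int, int]) -> str:
        """Concatenated grounding of every moment of one layer."""
        return "".join(
            "".join(self.trace_ground(key, tau))
            for tau in range(len(self.layers[key]))
        )

    # -- information accounting -------------------------------------------

    def layer_mean_ic(self, key: tuple[int, int]) -> float:
        from .bigram import mean_ic

        return mean_ic(self.layers[key].sequence())[0]

    def total_mean_ic(self) -> float:
        """Sum of per-layer mean information content over active layers."""
        return sum(self.layer_mean_ic(k) for k in self.active_keys())

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        from .bigram import BigramModel

        counts = []
        for key in sorted(self.layers):
            model = BigramModel.from_sequence(self.layers[key].sequence())
            for pred in sorted(model.counts):
                for succ in sorted(model.counts[pred]):
                    counts.append(
                        [list(key), pred, succ, model.counts[pred][succ]]
                    )
        return {
            "version": SCHEMA_VERSION,
            "config": self.config.to_dict(),
            "next_delta": self._next_delta,
            "stages": [
                {"base": list(st.base), "cat": list(st.cat) if st.cat else None}
                for st in self.stages
            ],
            "layers": [
                {
                    "delta": ly.delta,
                    "alpha": ly.alpha,
                    "kind": ly.kind,
                    "source": list(ly.source) if ly.source else None,
                    "moments": [[m.symbol_id, m.start, m.end] for m in ly.moments],
                    "alphabet": sorted(ly.alphabet),
                }
                for key, ly in sorted(self.layers.items())
            ],
            "pi": [
                [list(key), cat, members]
                for key in sorted(self.pi)
                for cat, members in sorted(self.pi[key].items())
            ],
            "lambda": [
                [list(key), chunk, list(content)]
                for key in sorted(self.lam)
                for chunk, content in sorted(self.lam[key].items())
            ],
            "counts": counts,
            "points": {
                str(i): {s: list(v) for s, v in sorted(pts.items())}
                for i, pts in sorted(self.points.items())
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Memory":
        if d.get("version") != SCHEMA_VERSION:
            raise IntegrityError(
                f"incompatible memory schema version {d.get('version')!r}"
            )
        mem = cls(RunConfig.from_dict(d["config"]))
        mem._next_delta = d["next_delta"]
        for ld in d["layers"]:
            ly = Layer(
                delta=ld["delta"],
                alpha=ld["alpha"],
                kind=ld["kind"],
                source=tuple(ld["source"]) if ld["source"] else None,
                moments=[
                    Moment(tau=i, symbol_id=s, start=a, end=b)
                    for i, (s, a, b) in enumerate(ld["moments"])
                ],
                alphabet=set(ld["alphabet"]),
            )
            mem.layers[ly.key] = ly
        mem.stages = [
            Stage(base=tuple(sd["base"]), cat=tuple(sd["cat"]) if sd["cat"] else None)
            for sd in d["stages"]
        ]
        for key, cat, members in d["pi"]:
            mem.pi.setdefault(tuple(key), {})[cat] = list(members)
        for key, chunk, content in d["lambda"]:
            mem.lam.setdefault(tuple(key), {})[chunk] = tuple(content)
        for i, pts in d.get("points", {}).items():
            mem.points[int(i)] = {s: list(v) for s, v in pts.items()}
        return mem

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_json(cls, text: str) -> "Memory":
        return cls.from_dict(json.loads(text))


def memory_from_symbols(ids: list[str] | str, config: Optional[RunConfig] = None) -> Memory:
    """Build a one-layer memory whose base layer holds the given symbols."""
    ids = list(ids)
    if not ids:
        raise ValueError("empty input")
    mem = Memory(config)
    base = mem.new_layer("base", alpha=0, source=None)
    for i, s in enumerate(ids):
        append_moment(base, Symbol(s, base.delta, base.alpha), (i, i + 1))
    mem.stages.append(Stage(base=base.key))
    return mem
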