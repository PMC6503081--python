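"""Token-position word-recovery scoring and the two chance baselines.

A gold token is *found* at level alpha when some moment at that level spans
exactly the token's character span; each token is credited once, at the
lowest such level.  Counting is over tokens (positions), not types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .corpus import GoldSegmentation
from .memory import Memory


class AlignmentError(ValueError):
    """The memory was not built over the gold's character stream."""


@dataclass
class LayerReport:
    """Per-level first-found token counts and percentages (Table-1 shape)."""

    n_tokens: int
    detector: str
    dataset: str
    levels: list[dict] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(lv["count"] for lv in self.levels)

    @property
    def total_percent(self) -> float:
        return 100.0 * self.total_count / self.n_tokens

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"level": lv["alpha"], "count": lv["count"], "percent": lv["percent"]}
            for lv in self.levels
        ]
        rows.append({"level": "total", "count": self.total_count,
                     "percent": self.total_percent})
        return pd.DataFrame(rows)


def score_tokens(memory: Memory, gold: GoldSegmentation,
                 dataset: str = "") -> LayerReport:
    """Score a built memory against gold word spans, crediting each token at
    the lowest level whose moment spans it exactly."""
    stream_len = len(memory.layers[memory.base_key])
    if gold.stream_length != stream_len:
        raise AlignmentError(
            f"gold stream length {gold.stream_length} != memory base length {stream_len}"
        )
    spans_by_alpha: dict[int, set[tuple[int, int]]] = {}
    for layer in memory.layers.values():
        spans = spans_by_alpha.setdefault(layer.alpha, set())
        for m in layer.moments:
            spans.add(m.span)
    alphas = sorted(spans_by_alpha)
    counts = {a: 0 for a in alphas}
    for token in gold.tokens:
        for a in alphas:
            if token.span in spans_by_alpha[a]:
                counts[a] += 1
                break
    n = len(gold)
    levels = [
        {"alpha": a, "count": counts[a], "percent": 100.0 * counts[a] / n}
        for a in alphas
    ]
    return LayerReport(n_tokens=n, detector=memory.config.detector,
                       dataset=dataset, levels=levels)


def _score_single_level(gold: GoldSegmentation, cuts: np.ndarray, L: int) -> float:
    bounds = np.concatenate(([0], np.sort(cuts), [L]))
    spans = set(zip(bounds[:-1].tolist(), bounds[1:].tolist()))
    hits = sum(1 for t in gold.tokens if t.span in spans)
    return 100.0 * hits / len(gold)


def chance_baseline(gold: GoldSegmentation, stream_length: int, variant: str,
                    reps: int = 100, seed: int = 0) -> float:
    """Mean token-recovery percentage of a random single-level segmentation.

    Variant "A" marks n-1 distinct boundaries at uniform random interior
    positions; variant "B" marks each of the L-1 interior positions
    independently with probability (n-1)/(L-1) (the observed boundary
    likelihood under a uniform assumption).  The mean over `reps` random
    segmentations is returned; deterministic per seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    n, L = len(gold), stream_length
    if n < 1:
        raise ValueError("empty gold segmentation")
    if n - 1 > L - 1:
        raise ValueError(f"cannot place {n - 1} boundaries in {L - 1} positions")
    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(reps):
        if variant == "A":
            cuts = rng.choice(np.arange(1, L), size=n - 1, replace=False)
        elif variant == "B":
            p = (n - 1) / (L - 1) if L > 1 else 0.0
            cuts = np.arange(1, L)[rng.random(L - 1) < p]
        else:
            raise ValueError(f"unknown baseline variant {variant!r}")
        scores.append(_score_single_level(gold, cuts, L))
    return float(np.mean(scores))
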