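"""Synthetic gold-annotated corpora.

Word-segmentation corpora are delimiter-free concatenations of a fixed
vocabulary sampled by (Zipf-skewed) weights, with exact gold spans.  The
prefix scenario builds a two-phase world for the re-segmentation study: a
phase in which negated "in"+adjective forms are only ever seen fused, and a
later evidence phase in which the prefix occurs free-standing, which should
let consolidation discover the prefix boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class GoldToken:
    word: str
    start: int
    end: int

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class GoldSegmentation:
    """Ordered gold tokens whose spans tile the stripped character stream."""

    tokens: list[GoldToken] = field(default_factory=list)

    @classmethod
    def from_words(cls, words: Sequence[str]) -> "GoldSegmentation":
        out, pos = [], 0
        for w in words:
            out.append(GoldToken(w, pos, pos + len(w)))
            pos += len(w)
        return cls(out)

    @property
    def stream_length(self) -> int:
        return self.tokens[-1].end if self.tokens else 0

    def __len__(self) -> int:
        return len(self.tokens)

    def to_list(self) -> list[list]:
        return [[t.word, t.start, t.end] for t in self.tokens]


@dataclass(frozen=True)
class VocabSpec:
    """A vocabulary of word forms with sampling weights.

    When frequencies is None, weights follow a Zipf law with the given
    exponent over the listed order (rank 1 = first word)."""

    words: tuple[str, ...]
    frequencies: Optional[tuple[float, ...]] = None
    zipf_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not self.words:
            raise ValueError("empty vocabulary")
        if len(set(self.words)) != len(self.words):
            raise ValueError("vocabulary words must be unique")
        if any(not w for w in self.words):
            raise ValueError("vocabulary words must be non-empty")
        if self.frequencies is not None:
            if len(self.frequencies) != len(self.words):
                raise ValueError("frequencies length mismatch")
            if min(self.frequencies) <= 0:
                raise ValueError("frequencies must be positive")

    def weights(self) -> np.ndarray:
        if self.frequencies is not None:
            w = np.asarray(self.frequencies, dtype=float)
        else:
            ranks = np.arange(1, len(self.words) + 1, dtype=float)
            w = ranks ** (-self.zipf_exponent)
        return w / w.sum()


def default_vocabulary(n_words: int = 20, min_len: int = 2, max_len: int = 9,
                       seed: int = 0) -> tuple[str, ...]:
    """A deterministic random vocabulary of unique lowercase words."""
    rng = np.random.default_rng(seed)
    letters = np.array(list("abcdefghijklmnopqrstuvwxyz"))
    words: list[str] = []
    seen = set()
    while len(words) < n_words:
        length = int(rng.integers(min_len, max_len + 1))
        w = "".join(rng.choice(letters, size=length))
        if w not in seen:
            seen.add(w)
            words.append(w)
    return tuple(words)


def generate_corpus(spec: VocabSpec, n_tokens: int
                    ) -> tuple[str, GoldSegmentation]:
    """Concatenate n_tokens weighted draws from the vocabulary, without
    delimiters; deterministic per spec.seed."""
    if n_tokens < 1:
        raise ValueError("n_tokens must be >= 1")
    rng = np.random.default_rng(spec.seed)
    idx = rng.choice(len(spec.words), size=n_tokens, p=spec.weights())
    words = [spec.words[i] for i in idx]
    return "".join(words), GoldSegmentation.from_words(words)


# -- the prefix re-segmentation scenario ------------------------------------

PREFIX = "in"
_ADJECTIVES = ("bcd", "fgh", "klm", "pqr", "vwx")
_I_FILLERS = ("zia", "zie", "zio", "ziu")   # keep i's successors varied
_T_FILLERS = ("sat", "set")                 # t-enders precede fused forms


@dataclass
class PrefixScenario:
    prefix: str
    adjectives: tuple[str, ...]
    fused_forms: tuple[str, ...]
    phase1_tokens: list[str]
    phase2_tokens: list[str]

    @property
    def phase1_text(self) -> str:
        return "".join(self.phase1_tokens)

    @property
    def phase2_text(self) -> str:
        return "".join(self.phase2_tokens)

    @property
    def phase1_gold(self) -> GoldSegmentation:
        return GoldSegmentation.from_words(self.phase1_tokens)

    @property
    def phase2_gold(self) -> GoldSegmentation:
        return GoldSegmentation.from_words(self.phase2_tokens)


def generate_prefix_scenario(n_adjectives: int,
                             order: tuple[str, str] = ("fused", "evidence"),
                             seed: int = 0) -> PrefixScenario:
    """Build the two-phase prefix world.

    Phase 1 ("fused") contains the positive and the fused negated form of
    each adjective (2n content forms) among fillers whose bigram statistics
    keep the fused forms unsegmented: every fused token follows a t-ending
    filler, and enough "zi·" fillers occur that h(n|i) = log2 7 bits exceeds
    the h(first-letter|n) = log2 n bits inside a fused form.  Phase 2
    ("evidence") adds free-standing "in" tokens (always followed by fillers)
    and more bare adjectives, reversing that inequality so a boundary fires
    after the prefix.  Filler multiplicities are fixed multiples of n derived
    from those inequalities.
    """
    if tuple(order) != ("fused", "evidence"):
        raise ValueError(
            "invalid phase order: fused exposure must precede the evidence phase"
        )
    n = n_adjectives
    if not 2 <= n <= len(_ADJECTIVES):
        raise ValueError(f"n_adjectives must be in 2..{len(_ADJECTIVES)}")
    rng = np.random.default_rng(seed)
    adjectives = _ADJECTIVES[:n]
    fused = tuple(PREFIX + a for a in adjectives)

    def shuffled(tokens: list) -> list:
        tokens = list(tokens)
        rng.shuffle(tokens)
        return tokens

    def weave(free: list[str], groups: list[list[str]]) -> list[str]:
        """Insert token groups at random slots between free tokens."""
        slots = sorted(rng.integers(0, len(free) + 1, size=len(groups)))
        out, prev = [], 0
        for slot, grp in zip(slots, groups):
            out.extend(free[prev:slot])
            out.extend(grp)
            prev = slot
        out.extend(free[prev:])
        return out

    # phase 1: 4 fused + 4 bare tokens per adjective; 6n of each zi-filler;
    # 16n each of sat/set, 4n of which immediately precede fused tokens
    free1 = shuffled(
        [a for a in adjectives for _ in range(4)]
        + [z for z in _I_FILLERS for _ in range(6 * n)]
        + [t for t in _T_FILLERS for _ in range(14 * n)]
    )
    fused_tokens = shuffled([f for f in fused for _ in range(4)])
    pairs1 = [[_T_FILLERS[i % 2], f] for i, f in enumerate(fused_tokens)]
    phase1 = weave(free1, pairs1)

    # phase 2: 8n free-standing prefixes each followed by a filler,
    # 2 extra bare tokens per adjective, plus filler padding
    followers = [(_I_FILLERS + _T_FILLERS)[i % 6] for i in range(8 * n)]
    pairs2 = [[PREFIX, f] for f in shuffled(followers)]
    free2 = shuffled(
        [a for a in adjectives for _ in range(2)]
        + [z for z in _I_FILLERS for _ in range(n)]
        + [t for t in _T_FILLERS for _ in range(5 * n)]
    )
    phase2 = weave(free2, pairs2)

    return PrefixScenario(prefix=PREFIX, adjectives=adjectives,
                          fused_forms=fused, phase1_tokens=phase1,
                          phase2_tokens=phase2)
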