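"""Text ingestion and memory persistence.

Ingestion follows the word-segmentation study's preprocessing: everything
but letters is removed, and the delimited original provides gold word spans
in the stripped stream.  Memories serialize to a JSON document that
round-trips bit-exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

from .corpus import GoldSegmentation, GoldToken
from .memory import Memory


def ingest_text(text: str, lowercase: bool = False
                ) -> tuple[str, GoldSegmentation]:
    """Strip a delimited text to its letter stream and derive gold spans.

    Words are maximal runs of alphabetic characters in the original; the
    returned stream is their delimiter-free concatenation.  Case folding is
    off by default.  Raises on an input with no letters.
    """
    if lowercase:
        text = text.lower()
    tokens: list[GoldToken] = []
    pos = 0
    current: list[str] = []

    def flush():
        nonlocal pos
        if current:
            w = "".join(current)
            tokens.append(GoldToken(w, pos, pos + len(w)))
            pos += len(w)
            current.clear()

    for ch in text:
        if ch.isalpha():
            current.append(ch)
        else:
            flush()
    flush()
    if not tokens:
        raise ValueError("input contains no letters after stripping")
    stream = "".join(t.word for t in tokens)
    return stream, GoldSegmentation(tokens)


def ingest_file(path: str | Path, lowercase: bool = False,
                encoding: str = "utf-8") -> tuple[str, GoldSegmentation]:
    return ingest_text(Path(path).read_text(encoding=encoding), lowercase)


def save_memory(memory: Memory, path: str | Path) -> None:
    Path(path).write_text(memory.to_json(), encoding="utf-8")


def load_memory(path: str | Path) -> Memory:
    """Load a serialized memory; a truncated or incompatible file raises
    before any partial memory is returned."""
    return Memory.from_json(Path(path).read_text(encoding="utf-8"))


def gold_to_json(gold: GoldSegmentation) -> list[list]:
    return gold.to_list()


def gold_from_json(data: list[list]) -> GoldSegmentation:
    return GoldSegmentation([GoldToken(w, a, b) for w, a, b in data])
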