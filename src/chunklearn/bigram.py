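"""First-order transition statistics and the information measures H, h, h-bar.

Every layer of the memory is scored by a bigram model over its own alphabet,
with a start sentinel prepended so the first moment has a defined information
content.  Static models use maximum-likelihood counts from the whole sequence;
online models predict before learning and apply add-one smoothing over the
current alphabet plus one novelty slot.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from typing import Iterable, Optional

from .memory import SENTINEL, AlphabetError


class BigramModel:
    """Per-layer contiguous-pair counts.

    In static mode an unseen context yields an *undefined* distribution
    (returned as None, distinct from an empty one) and a zero-probability
    transition yields infinite information content.  In online mode smoothing
    keeps every prediction defined.
    """

    def __init__(self, mode: str = "static", smoothing: bool = True,
                 alphabet: Optional[set[str]] = None):
        if mode not in ("static", "online"):
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode
        self.smoothing = smoothing
        self.allowed = set(alphabet) if alphabet is not None else None
        self.counts: dict[str, Counter] = defaultdict(Counter)
        self.totals: Counter = Counter()
        self.alphabet: set[str] = set()

    @classmethod
    def from_sequence(cls, ids: Iterable[str], mode: str = "static",
                      smoothing: bool = True) -> "BigramModel":
        model = cls(mode=mode, smoothing=smoothing)
        prev = SENTINEL
        for s in ids:
            model.update(prev, s)
            prev = s
        return model

    # -- counting ---------------------------------------------------------

    def update(self, pred: str, succ: str) -> None:
        """Record one contiguous pair (the sentinel may appear as pred)."""
        if self.allowed is not None:
            for s in (pred, succ):
                if s != SENTINEL and s not in self.allowed:
                    raise AlphabetError(f"symbol {s!r} is not in this layer's alphabet")
        self.counts[pred][succ] += 1
        self.totals[pred] += 1
        self.alphabet.add(succ)
        if pred != SENTINEL:
            self.alphabet.add(pred)

    # -- probabilities ----------------------------------------------------

    def _smoothed(self, pred: str, succ: str) -> float:
        k = len(self.alphabet) + 1  # current alphabet plus one novelty slot
        return (self.counts[pred][succ] + 1) / (self.totals[pred] + k)

    def prob(self, pred: str, succ: str) -> Optional[float]:
        """p(succ | pred); None when the context is undefined (static mode)."""
        if self.mode == "online" and self.smoothing:
            return self._smoothed(pred, succ)
        total = self.totals.get(pred, 0)
        if total == 0:
            return None
        return self.counts[pred][succ] / total

    def distribution(self, context: str) -> Optional[dict[str, float]]:
        """The successor distribution D for a context symbol.

        Static mode returns None for a context never seen as the first
        element of a bigram (an undefined-context signal, not an empty
        distribution).  Online mode smooths over the alphabet plus a novelty
        slot written as "".
        """
        if self.mode == "online" and self.smoothing:
            k = len(self.alphabet) + 1
            total = self.totals.get(context, 0)
            dist = {s: (self.counts[context][s] + 1) / (total + k) for s in self.alphabet}
            dist[""] = 1 / (total + k)  # novelty slot
            return dist
        total = self.totals.get(context, 0)
        if total == 0:
            return None
        return {s: c / total for s, c in self.counts[context].items()}

    # -- information measures ---------------------------------------------

    def entropy(self, context: str) -> Optional[float]:
        """Shannon entropy H of the successor distribution, in bits."""
        dist = self.distribution(context)
        if dist is None:
            return None
        return -sum(p * math.log2(p) for p in dist.values() if p > 0.0) + 0.0

    def information_content(self, pred: str, succ: str) -> Optional[float]:
        """h = -log2 p(succ | pred); inf for an unseen transition in static
        mode, None for an undefined context."""
        p = self.prob(pred, succ)
        if p is None:
            return None
        if p == 0.0:
            return math.inf
        return -math.log2(p) + 0.0  # avoid -0.0 for certain transitions

    def h_profile(self, ids: list[str]) -> list[Optional[float]]:
        """Moment-wise information content of a sequence under this model,
        with the sentinel as predecessor of the first moment."""
        out = []
        prev = SENTINEL
        for s in ids:
            out.append(self.information_content(prev, s))
            prev = s
        return out

    def entropy_profile(self, ids: list[str]) -> list[Optional[float]]:
        """Moment-wise entropy: H at tau is the uncertainty about tau+1 given
        the symbol observed at tau."""
        return [self.entropy(s) for s in ids]

    def max_entropy(self) -> float:
        """The uniform-distribution bound log2 |A| for this alphabet."""
        return math.log2(len(self.alphabet)) if self.alphabet else 0.0


def mean_ic(ids: list[str]) -> tuple[float, int]:
    """Static-mode mean information content h-bar of a sequence, in bits.

    Returns (h-bar over moments with defined h, number of undefined moments).
    Raises on an empty sequence.  With the start sentinel and a model built
    from the sequence itself, every moment is defined.
    """
    ids = list(ids)
    if not ids:
        raise ValueError("h-bar is undefined for an empty layer")
    model = BigramModel.from_sequence(ids)
    profile = model.h_profile(ids)
    defined = [h for h in profile if h is not None]
    n_undef = len(profile) - len(defined)
    if not defined:
        raise ValueError("no moment has defined information content")
    return sum(defined) / len(defined), n_undef


def online_profiles(ids: list[str], smoothing: bool = True
                    ) -> tuple[list[Optional[float]], list[Optional[float]]]:
    """Predict-then-learn h and H profiles for an incrementally read sequence.

    h at tau uses the model state before the pair (tau-1, tau) is counted;
    H at tau uses the state just after, i.e. the prediction of tau+1 made
    during moment tau.
    """
    model = BigramModel(mode="online", smoothing=smoothing)
    h: list[Optional[float]] = []
    H: list[Optional[float]] = []
    prev = SENTINEL
    for s in ids:
        h.append(model.information_content(prev, s))
        model.update(prev, s)
        H.append(model.entropy(s))
        prev = s
    return h, H


def static_profiles(ids: list[str]
                    ) -> tuple[list[Optional[float]], list[Optional[float]]]:
    """Post-hoc h and H profiles under the model of the full sequence."""
    model = BigramModel.from_sequence(ids)
    return model.h_profile(ids), model.entropy_profile(ids)
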