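"""Geometric semantic memory: vector spaces, spectral abstraction of
trajectories, and the convexity gate on candidate categories.

A space is a set of points (one per alphabet symbol), an inner product drawn
from a small library, and the norm it induces.  Concepts are regions with
centroid prototypes; a candidate category is vetoed when an outside point
falls inside the rho-expanded hull of the candidate set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class ConvexityParams:
    """rho expands the hull around candidate points; larger rho makes the
    gate more willing to reject categorizations."""

    rho: float = 0.0

    def __post_init__(self):
        if self.rho < 0:
            raise ValueError("rho must be non-negative")


class SemanticSpace:
    """Points for one alphabet plus a choice of inner product.

    inner_product: "dot" (unweighted), "cosine" (points normalized to unit
    length first) or "diag" (diagonally weighted; weights default to ones).
    """

    def __init__(self, points: dict[str, Sequence[float]],
                 inner_product: str = "dot",
                 weights: Optional[Sequence[float]] = None):
        if inner_product not in ("dot", "cosine", "diag"):
            raise ValueError(f"unknown inner product {inner_product!r}")
        self.inner_product = inner_product
        self.points = {s: np.asarray(v, dtype=float) for s, v in points.items()}
        dims = {v.shape for v in self.points.values()}
        if len(dims) > 1:
            raise ValueError("points have inconsistent dimension")
        self.weights = None if weights is None else np.asarray(weights, dtype=float)

    def _vec(self, sym_or_vec) -> np.ndarray:
        if isinstance(sym_or_vec, str):
            v = self.points[sym_or_vec]
        else:
            v = np.asarray(sym_or_vec, dtype=float)
        if self.inner_product == "cosine":
            n = math.sqrt(float(v @ v))
            if n > 0:
                v = v / n
        return v

    def ip(self, u, v) -> float:
        u, v = self._vec(u), self._vec(v)
        if self.inner_product == "diag" and self.weights is not None:
            return float(u @ (self.weights * v))
        return float(u @ v)

    def norm(self, v) -> float:
        return math.sqrt(max(self.ip(v, v), 0.0))

    def distance(self, u, v) -> float:
        return self.norm(np.asarray(self._vec(u)) - np.asarray(self._vec(v)))

    def centroid(self, members: Iterable[str]) -> np.ndarray:
        vecs = [self._vec(s) for s in members]
        if not vecs:
            raise ValueError("centroid of an empty set")
        return np.mean(vecs, axis=0)


def spectral_abstract(trajectory: Sequence[Sequence[float]], k: int) -> np.ndarray:
    """Abstract an ordered trajectory of vectors to one fixed-length point.

    The default transform is a discrete Fourier transform per input
    dimension; the first k coefficients (zero-padded when the trajectory is
    shorter) are stored as interleaved real/imaginary parts, so sequences of
    any length become comparable points of dimension 2*k*D.
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.ndim == 1:
        traj = traj[:, None]
    if traj.size == 0:
        raise ValueError("cannot abstract an empty trajectory")
    n, d = traj.shape
    coeffs = np.zeros((k, d), dtype=complex)
    spec = np.fft.fft(traj, axis=0)
    m = min(k, n)
    coeffs[:m] = spec[:m]
    out = np.empty(2 * k * d)
    out[0::2] = coeffs.real.T.ravel()
    out[1::2] = coeffs.imag.T.ravel()
    return out


def convexity_gate(space: SemanticSpace, candidate_members: Sequence[str],
                   params: ConvexityParams) -> bool:
    """True iff the candidate set may be categorized together.

    The hull is approximated by the ball of radius (max member-to-centroid
    distance + rho) around the centroid; the gate fails iff any alphabet
    point outside the candidate set falls inside it.  Rejection is monotone
    in rho.
    """
    members = list(candidate_members)
    if not members:
        raise ValueError("empty candidate set")
    centroid = space.centroid(members)
    hull = max(space.distance(s, centroid) for s in members) + params.rho
    for s in space.points:
        if s in members:
            continue
        if space.distance(s, centroid) <= hull:
            return False
    return True


def indicator_space(alphabet: Iterable[str],
                    inner_product: str = "dot") -> SemanticSpace:
    """Orthonormal indicator points, one axis per symbol (sorted order)."""
    syms = sorted(set(alphabet))
    eye = np.eye(len(syms))
    return SemanticSpace({s: eye[i] for i, s in enumerate(syms)},
                         inner_product=inner_product)
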