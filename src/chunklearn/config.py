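"""Run configuration shared by the whole pipeline."""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


_DETECTORS = ("simple", "complex")
_MODES = ("static", "online")
_SPACE_MODES = ("equality", "indicator", "custom")
_INNER_PRODUCTS = ("dot", "cosine", "diag")


@dataclass(frozen=True)
class RunConfig:
    """Parameters controlling learning, categorization and consolidation.

    detector:       boundary detector id; "simple" flags a rise in information
                    content h, "complex" combines entropy H and h.
    mode:           "static" builds the bigram model post hoc from the whole
                    layer; "online" updates it incrementally (predict-then-learn).
    boundary_shift: False reads a true flag at tau as "close the current
                    segment after tau"; True as the literal "tau starts a
                    new segment".
    max_levels:     cap on the number of stacked chunk layers.
    rho:            convexity radius; larger values reject more categorizations.
    spectral_k:     number of Fourier coefficients kept per input dimension
                    when abstracting trajectories to points.
    space_mode:     "equality" disables geometric categorization (identity
                    gate, the text default); "indicator" uses orthonormal
                    indicator points; "custom" uses user-supplied points.
    smoothing:      add-one smoothing for online predictions.
    seed:           seed recorded for provenance and used by any stochastic step.
    budget:         default consolidation iteration budget.
    """

    detector: str = "simple"
    mode: str = "static"
    boundary_shift: bool = False
    max_levels: int = 8
    rho: float = 0.0
    spectral_k: int = 4
    space_mode: str = "equality"
    inner_product: str = "dot"
    smoothing: bool = True
    seed: int = 0
    budget: int = 50

    def validate(self) -> "RunConfig":
        if self.detector not in _DETECTORS:
            raise ConfigError(f"unknown detector {self.detector!r}")
        if self.mode not in _MODES:
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.space_mode not in _SPACE_MODES:
            raise ConfigError(f"unknown space mode {self.space_mode!r}")
        if self.inner_product not in _INNER_PRODUCTS:
            raise ConfigError(f"unknown inner product {self.inner_product!r}")
        if self.rho < 0:
            raise ConfigError("rho must be non-negative")
        if self.max_levels < 1:
            raise ConfigError("max_levels must be positive")
        if self.spectral_k < 1:
            raise ConfigError("spectral_k must be positive")
        if self.budget < 0:
            raise ConfigError("budget must be non-negative")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d).validate()

    def with_(self, **kw) -> "RunConfig":
        return replace(self, **kw).validate()
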