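"""Stimulus building components (SBCs): registry, specs and validation.

A stimulus is assembled from typed, parameterized building components rather
than written as code: *primers* produce pixel colors (shapes, patterns,
checkerboards, images), and are decorated by *motion*, *modulation* and
*warp* components; *composition* components mix primers through a mask;
*spatial_filter*, *temporal_filter*, *tonemap* and *gamma* components form
the post-processing chain.  Every concrete component is registered under its
``(sbc_type, name)`` pair with a full table of documented parameter
defaults; unknown names and unknown parameters are rejected at validation
time, never silently ignored.
"""

from __future__ import annotations

import dataclasses
from typing import Any

SBC_TYPES = (
    "primer",
    "motion",
    "modulation",
    "warp",
    "composition",
    "prng",
    "spatial_filter",
    "temporal_filter",
    "tonemap",
    "gamma",
)

_REGISTRY: dict[tuple[str, str], type] = {}


def register(sbc_type: str, name: str):
    """Class decorator registering a concrete component implementation."""
    if sbc_type not in SBC_TYPES:
        raise ValueError(f"unknown sbc_type {sbc_type!r}")

    def wrap(cls):
        cls.sbc_type = sbc_type
        cls.name = name
        _REGISTRY[(sbc_type, name)] = cls
        return cls

    return wrap


def registered_names(sbc_type: str | None = None) -> list[tuple[str, str]]:
    keys = sorted(_REGISTRY)
    if sbc_type is not None:
        keys = [k for k in keys if k[0] == sbc_type]
    return keys


def lookup(sbc_type: str, name: str) -> type:
    try:
        return _REGISTRY[(sbc_type, name)]
    except KeyError:
        known = ", ".join(n for t, n in registered_names(sbc_type)) or "(none)"
        raise KeyError(
            f"no {sbc_type} component named {name!r}; known: {known}"
        ) from None


class Component:
    """Base class for concrete SBCs.

    Subclasses declare ``DEFAULTS``, a mapping of every accepted parameter to
    its default value.  Construction merges user parameters over the
    defaults and rejects unknown keys.
    """

    sbc_type: str
    name: str
    DEFAULTS: dict[str, Any] = {}

    def __init__(self, **params: Any) -> None:
        unknown = set(params) - set(self.DEFAULTS)
        if unknown:
            raise ValueError(
                f"{self.sbc_type}/{self.name}: unknown parameter(s) "
                f"{sorted(unknown)}; accepted: {sorted(self.DEFAULTS)}"
            )
        self.params = {**self.DEFAULTS, **params}
        self._validate()

    def _validate(self) -> None:  # overridden where constraints exist
        pass

    def prepare(self, t_frame: int, ctx) -> None:
        """Per-frame prerequisite hook (PRNG advance etc.); default no-op."""

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<{self.sbc_type}/{self.name} {self.params}>"


@dataclasses.dataclass
class ComponentSpec:
    """Declarative description of one SBC: type, concrete name, parameters."""

    sbc_type: str
    name: str
    params: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sbc_type not in SBC_TYPES:
            raise ValueError(f"unknown sbc_type {self.sbc_type!r}")
        lookup(self.sbc_type, self.name)  # raises for unregistered names

    def build(self) -> Component:
        return lookup(self.sbc_type, self.name)(**self.params)

    def resolved_params(self) -> dict[str, Any]:
        """Parameters with every documented default filled in."""
        return dict(self.build().params)


@dataclasses.dataclass
class StimulusSpec:
    """An ordered component list plus a duration, forming one stimulus."""

    components: list[ComponentSpec]
    duration_frames: int
    label: str = "stimulus"

    def __post_init__(self) -> None:
        if int(self.duration_frames) < 1:
            raise ValueError("duration_frames must be >= 1")
        n_temporal = sum(1 for c in self.components if c.sbc_type == "temporal_filter")
        n_gamma = sum(1 for c in self.components if c.sbc_type == "gamma")
        if n_temporal > 1:
            raise ValueError("at most one temporal_filter per stimulus")
        if n_gamma > 1:
            raise ValueError("at most one gamma per stimulus")
        primer_indices = [
            i for i, c in enumerate(self.components) if c.sbc_type == "primer"
        ]
        for c in self.components:
            if c.sbc_type == "composition":
                p = c.resolved_params()
                for key in ("foreground", "background", "mask"):
                    idx = p[key]
                    if idx not in primer_indices:
                        raise ValueError(
                            f"composition {key}={idx} does not reference a "
                            f"primer component (primers at {primer_indices})"
                        )

    def duration_s(self, geometry) -> float:
        return self.duration_frames / geometry.frame_rate_hz
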