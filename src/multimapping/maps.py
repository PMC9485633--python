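"""Pixelwise parameter maps with units and provenance."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ParameterMap"]


@dataclass
class ParameterMap:
    """A 2D quantitative map (T1, T2 or ECV) with units and metadata.

    Invalid pixels (unfitted, flagged, outside the mask) are NaN.
    """

    data: np.ndarray
    units: str
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 2:
            raise ValueError(f"parameter map must be 2D, got shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.data)
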