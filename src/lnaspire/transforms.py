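"""Channel-value transforms.

Fluorescence intensities are analyzed on the inverse-hyperbolic-sine scale
``t(x) = asinh(x / cofactor)`` with a default cofactor of 150, the common
choice for conventional (non-spectral) cytometers: near zero the scale is
linear, for large values it is logarithmic.  Scatter channels stay linear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TransformSpec:
    name: str = "arcsinh"
    cofactor: float = 150.0

    def __post_init__(self) -> None:
        if self.name != "arcsinh":
            raise ValueError(f"unsupported transform {self.name!r}")
        if self.cofactor <= 0:
            raise ValueError("cofactor must be positive")

    def forward(self, x):
        return np.arcsinh(np.asarray(x, dtype=float) / self.cofactor)

    def inverse(self, y):
        return np.sinh(np.asarray(y, dtype=float)) * self.cofactor


DEFAULT_TRANSFORM = TransformSpec()
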