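"""Aggregate model parameters with the fitted defaults.

``ModelParams`` bundles the membrane, threshold and latency constants with
the action-potential initiation duration ``phi`` and the numerical
controls (evaluation grid step, component cap ``k_max``).  The defaults
instantiate the fitted single-fiber parameterization; any field can be
overridden for sensitivity studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .membrane import DEFAULT_GRID_STEP, MembraneParams
from .pulse_response import LatencyParams
from .threshold_state import ThresholdParams

__all__ = ["ModelParams"]


@dataclass(frozen=True)
class ModelParams:
    membrane: MembraneParams = field(default_factory=MembraneParams)
    threshold: ThresholdParams = field(default_factory=ThresholdParams)
    latency: LatencyParams = field(default_factory=LatencyParams)
    #: action-potential initiation duration (s)
    phi: float = 20.5e-6
    #: evaluation and reporting grid step (s)
    grid_step: float = DEFAULT_GRID_STEP
    #: maximum number of threshold-mixture components
    k_max: int = 20

    def __post_init__(self) -> None:
        if not self.phi > 0:
            raise ValueError("phi must be positive")
        if not self.grid_step > 0:
            raise ValueError("grid_step must be positive")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")

    def with_k_max(self, k_max: int) -> "ModelParams":
        return replace(self, k_max=k_max)
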