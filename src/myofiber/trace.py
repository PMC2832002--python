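"""Force-trace container.

A :class:`ForceTrace` is a uniformly sampled force-time record from a single
permeabilized-fiber protocol run (caged-Ca2+ photolysis, caged-ATP photolysis
from Ca2+-rigor, or a rapid length release), together with the metadata needed
to interpret it: surgery group, pCa, added phosphate and ADP, and the sampling
rate. Forces are normalized to fiber cross-sectional area (mN/mm^2); time is
in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ForceTrace"]


@dataclass
class ForceTrace:
    time_s: np.ndarray
    force: np.ndarray  # mN/mm^2
    protocol_kind: str = "CA_JUMP"  # CA_JUMP | ATP_JUMP | LENGTH_RELEASE
    fiber_id: str = ""
    group: str = ""
    pCa: float = 4.5
    pi_mM: float = 0.0
    adp_mM: float = 0.0
    rate_hz: float = 1000.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.time_s.shape != self.force.shape:
            raise ValueError("time and force arrays must have equal length")
        if self.time_s.ndim != 1:
            raise ValueError("trace arrays must be one-dimensional")

    def __len__(self) -> int:
        return self.time_s.size

    @property
    def duration(self) -> float:
        return float(self.time_s[-1] - self.time_s[0]) if len(self) else 0.0

    def metadata(self) -> dict:
        """Metadata dict used by the text serialization header."""
        md = {
            "fiber_id": self.fiber_id,
            "group": self.group,
            "protocol": self.protocol_kind,
            "pCa": self.pCa,
            "pi_mM": self.pi_mM,
            "adp_mM": self.adp_mM,
            "rate_hz": self.rate_hz,
        }
        md.update(self.extra)
        return md
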