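"""Body poses and their gravity directions in the torso-fixed frame.

The torso frame is +x left, +y superior, +z anterior.  Differences between
arm positions (S vs SS vs SU) are modelled purely as gravity-direction
changes; no musculoskeletal arm model is attempted.

- PRONE (face-down MRI position): gravity pulls the breast anteriorly, +z.
- SS / SU (supine, face-up): gravity pulls posteriorly, -z.
- S (standing): gravity pulls inferiorly, -y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PoseCase", "STANDARD_POSES", "GRAVITY_MS2"]

#: Standard gravitational acceleration, m/s^2.
GRAVITY_MS2 = 9.81

_UNIT_TOL = 1e-12


@dataclass(frozen=True)
class PoseCase:
    """A body pose label plus its unit gravity direction in the torso frame."""

    label: str  # one of S, SS, SU, PRONE (free labels allowed for experiments)
    gravity: np.ndarray  # unit 3-vector

    def __post_init__(self):
        g = np.asarray(self.gravity, dtype=np.float64).reshape(3)
        n = np.linalg.norm(g)
        if abs(n - 1.0) > 1e-6:
            raise ValueError(f"gravity must be a unit vector, |g| = {n}")
        g = g / n  # renormalise to machine precision
        object.__setattr__(self, "gravity", g)

    def gravity_ms2(self, magnitude: float = GRAVITY_MS2) -> np.ndarray:
        """Gravity vector scaled to physical magnitude (m/s^2)."""
        return self.gravity * magnitude


STANDARD_POSES = {
    "PRONE": PoseCase("PRONE", np.array([0.0, 0.0, 1.0])),
    "SS": PoseCase("SS", np.array([0.0, 0.0, -1.0])),
    "SU": PoseCase("SU", np.array([0.0, 0.0, -1.0])),
    "S": PoseCase("S", np.array([0.0, -1.0, 0.0])),
}
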