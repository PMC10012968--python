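"""Gravity direction and height conventions for body postures.

Anatomical coordinates are fixed: x runs left (-) to right (+), y runs
ventral (-) to dorsal (+), z runs caudal (-) to cranial (+).  A posture is a
gravity magnitude plus a unit vector pointing "down" in these coordinates.
Gravitational height of a point is its projection onto the "up" direction,
referenced to the most dependent point of whatever structure is being
analysed (so heights are always >= 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

G_EARTH = 9.81  # m/s^2

#: gravity ("down") unit vectors per posture, anatomical coordinates
_GRAVITY_DIRECTIONS = {
    "zero_g": (0.0, 0.0, -1.0),  # direction is irrelevant when g = 0
    "upright": (0.0, 0.0, -1.0),  # down = caudal
    "supine": (0.0, 1.0, 0.0),  # lying on the back: down = dorsal
    "prone": (0.0, -1.0, 0.0),  # lying on the front: down = ventral
    "right_lateral": (1.0, 0.0, 0.0),  # lying on the right side: down = right
}

POSTURE_NAMES = tuple(_GRAVITY_DIRECTIONS)


@dataclass(frozen=True)
class PostureContext:
    """Gravity magnitude and direction defining heights and cos(theta) terms."""

    name: str
    g: float
    gravity_dir: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, -1.0]))

    def __post_init__(self):
        d = np.asarray(self.gravity_dir, dtype=float)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or n == 0.0:
            raise ValueError("gravity direction must be a nonzero vector")
        object.__setattr__(self, "gravity_dir", d / n)
        if self.g < 0.0:
            raise ValueError("gravity magnitude must be >= 0")

    @classmethod
    def from_name(cls, name: str, g: float | None = None) -> "PostureContext":
        if name not in _GRAVITY_DIRECTIONS:
            raise ValueError(f"unknown posture {name!r}; choose from {POSTURE_NAMES}")
        mag = 0.0 if name == "zero_g" else (G_EARTH if g is None else g)
        return cls(name=name, g=mag, gravity_dir=np.array(_GRAVITY_DIRECTIONS[name]))

    @property
    def up(self) -> np.ndarray:
        return -self.gravity_dir

    def heights(self, positions: np.ndarray) -> np.ndarray:
        """Gravitational height (m) of points, zero at the most dependent one."""
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        h = pos @ self.up
        return h - h.min()

    def cos_theta(self, start: np.ndarray, end: np.ndarray) -> np.ndarray:
        """cos of the angle between segment direction(s) and the ascending
        (anti-gravity) direction.

        Positive when the segment points uphill, so that
        ``rho * g * L * cos_theta`` is the hydrostatic pressure *drop* along
        the segment in the flow direction (blood loses static pressure
        climbing against gravity, gains it descending).
        """
        d = np.atleast_2d(np.asarray(end, float) - np.asarray(start, float))
        length = np.linalg.norm(d, axis=1)
        out = np.zeros(len(d))
        ok = length > 0
        out[ok] = (d[ok] @ self.up) / length[ok]
        return out
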