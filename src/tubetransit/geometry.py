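"""Simulation domain: two Eustachian tubes joined by a nasopharynx cavity.

The default dimensions describe the rat anatomy used throughout the
package: each tube is a cylinder 1.5 mm long with radius 0.05 mm, and the
nasopharynx is a 1 mm cube whose opposing faces carry the tube mouths,
centred on the common x axis.  The axis runs from the ipsilateral source
plane (x = 0) to the contralateral absorbing plane
(x = 2 * tube_length + cavity_side = 4.0 mm at defaults).

A ``straight_channel`` variant replaces the cavity by a cylinder of the
same tube radius, making the whole domain one cylinder; its x-marginal is
exactly a 1-D drift-diffusion process (cylinder-wall reflections have
radial normals and never change x), which is what the PDE oracle checks.

Public coordinates are in millimetres; kernels run in metres.
"""

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from . import _kernels
from .errors import ValidationError

MM = 1e-3  # metres per millimetre

_REGION_NAMES = ("ipsi_tube", "cavity", "contra_tube", "outside")
_MODES = ("two_tube_cavity", "straight_channel")


@dataclass(frozen=True)
class Geometry:
    """Axial two-tube-plus-cavity domain (lengths in mm)."""

    mode: str = "two_tube_cavity"
    tube_length: float = 1.5
    tube_radius: float = 0.05
    cavity_side: float = 1.0

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValidationError(
                f"mode must be one of {_MODES}, got {self.mode!r}")
        for name in ("tube_length", "tube_radius", "cavity_side"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValidationError(
                    f"{name} must be strictly positive, got {value!r}")
        if 2 * self.tube_radius > self.cavity_side:
            raise ValidationError(
                "tube_radius: tube mouth (diameter "
                f"{2 * self.tube_radius} mm) does not fit on the cavity "
                f"face (side {self.cavity_side} mm)")

    # -- axial landmarks (mm) ------------------------------------------
    @property
    def x_source(self) -> float:
        return 0.0

    @property
    def x_in(self) -> float:
        return self.tube_length

    @property
    def x_out(self) -> float:
        return self.tube_length + self.cavity_side

    @property
    def x_absorb(self) -> float:
        return 2 * self.tube_length + self.cavity_side

    @cached_property
    def _params(self):
        """Kernel parameter tuple, in metres."""
        mode = (_kernels.STRAIGHT if self.mode == "straight_channel"
                else _kernels.TWO_TUBE)
        return (mode, self.tube_radius * MM, self.x_in * MM,
                self.x_out * MM, self.x_absorb * MM,
                0.5 * self.cavity_side * MM)

    # -- membership ----------------------------------------------------
    def contains(self, point_mm) -> bool:
        """True iff the point (mm) lies in the closed domain."""
        x, y, z = (float(c) * MM for c in point_mm)
        return bool(_kernels.contains_pt(*self._params, x, y, z))

    def region_of(self, point_mm) -> str:
        """Label a point as ipsi_tube / cavity / contra_tube / outside.

        Axial boundary planes belong to the downstream (+x) region.
        """
        x, y, z = (float(c) * MM for c in point_mm)
        return _REGION_NAMES[_kernels.region_pt(*self._params, x, y, z)]

    def reflect_segment(self, p_from_mm, p_to_mm):
        """Wall-correct the segment p_from -> p_to by specular reflection.

        Returns ``(endpoint_mm, n_reflections)``.  If the trajectory
        reaches the absorbing plane the endpoint lies on it.  If more
        than 8 reflections are needed, the move is rejected and
        ``p_from`` is returned (the caller should resample the step).
        """
        p0 = np.asarray(p_from_mm, dtype=float)
        p1 = np.asarray(p_to_mm, dtype=float)
        if not np.all(np.isfinite(p0)) or not np.all(np.isfinite(p1)):
            raise ValidationError("segment endpoints must be finite")
        if not self.contains(p0):
            raise ValidationError(
                f"p_from {tuple(p0)} lies outside the domain")
        d = (p1 - p0) * MM
        x, y, z, _absorbed, nrefl, fallback = _kernels.advance(
            *self._params, p0[0] * MM, p0[1] * MM, p0[2] * MM,
            d[0], d[1], d[2])
        if fallback:
            return p0.copy(), nrefl
        return np.array([x, y, z]) / MM, nrefl


def build_paper_geometry(**overrides) -> Geometry:
    """Default rat-anatomy geometry (1.5 / 0.05 / 1.0 mm), with overrides."""
    return Geometry(**overrides)
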