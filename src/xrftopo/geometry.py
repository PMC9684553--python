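"""Detector geometry for the eight-SDD compass arrangement.

Each silicon drift detector is described by its face center, the unit
normal (aimed at the sample), the square face side and the number of
ray-target points spread over the face.  Because the sample (tens of
um) is tiny compared to the detector distance (tens of mm), the solid
angle fraction is taken constant per detector in the far-field
approximation Omega/4pi = A cos(gamma) / (4 pi d^2), evaluated from the
grid center; with the face aimed at the sample cos(gamma) = 1.

Compass convention (matching the package's (z, y, x) arrays): pixel
(0, 0) is the North-West corner, x increases East, y increases South;
North is -y.  Azimuth is measured clockwise from North, so N=0, E=90,
S=180, W=270.  Elevation is the angle above the support plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DetectorSpec", "default_detectors", "COMPASS_AZIMUTHS"]

COMPASS_AZIMUTHS = {
    "N": 0.0, "NE": 45.0, "E": 90.0, "SE": 135.0,
    "S": 180.0, "SW": 225.0, "W": 270.0, "NW": 315.0,
}


@dataclass(frozen=True)
class DetectorSpec:
    """Geometry of one SDD face in the sample frame (um)."""

    name: str
    azimuth_deg: float
    elevation_deg: float = 30.0
    distance_um: float = 28000.0
    face_side_um: float = 5000.0
    n_face_points: int = 9
    anchor_xy: tuple[float, float] = (20.0, 20.0)  # grid footprint center

    def __post_init__(self):
        if self.n_face_points < 1:
            raise ValueError("n_face_points must be >= 1")
        k = int(round(np.sqrt(self.n_face_points)))
        if k * k != self.n_face_points:
            raise ValueError("n_face_points must be a perfect square")
        if self.elevation_deg <= 0:
            raise ValueError("face center must sit strictly above the support plane")

    @property
    def horizontal_dir(self) -> np.ndarray:
        """Unit (x, y) direction from the sample toward the detector."""
        az = np.radians(self.azimuth_deg)
        return np.array([np.sin(az), -np.cos(az)])

    @property
    def face_center(self) -> np.ndarray:
        el = np.radians(self.elevation_deg)
        ux, uy = self.horizontal_dir
        ax, ay = self.anchor_xy
        d = self.distance_um
        return np.array(
            [ax + d * np.cos(el) * ux, ay + d * np.cos(el) * uy, d * np.sin(el)]
        )

    @property
    def normal(self) -> np.ndarray:
        """Unit normal of the face, aimed at the sample anchor."""
        c = self.face_center
        v = np.array([self.anchor_xy[0], self.anchor_xy[1], 0.0]) - c
        return v / np.linalg.norm(v)

    @property
    def solid_angle_fraction(self) -> float:
        a = self.face_side_um**2
        return float(a / (4.0 * np.pi * self.distance_um**2))

    def face_targets(self) -> np.ndarray:
        """Deterministic uniform grid of ray targets on the face,
        shape (n_face_points, 3)."""
        n = self.normal
        up = np.array([0.0, 0.0, 1.0])
        v1 = np.cross(n, up)
        v1 /= np.linalg.norm(v1)
        v2 = np.cross(n, v1)
        k = int(round(np.sqrt(self.n_face_points)))
        offs = ((np.arange(k) + 0.5) / k - 0.5) * self.face_side_um
        c = self.face_center
        pts = [c + a * v1 + b * v2 for a in offs for b in offs]
        return np.array(pts)

    def mean_cosec_phi(self, pixel_xy) -> float:
        """Mean cosecant of the take-off angles from a pixel (on the
        support plane) to the face ray targets; the <cosec(phi)>_alpha
        of the closed-form absorption factor."""
        p = np.array([pixel_xy[0], pixel_xy[1], 0.0])
        v = self.face_targets() - p
        sin_phi = v[:, 2] / np.linalg.norm(v, axis=1)
        return float(np.mean(1.0 / sin_phi))


def default_detectors(
    extent_xy_um: tuple[float, float] = (40.0, 40.0),
    elevation_deg: float = 30.0,
    distance_um: float = 28000.0,
    face_side_um: float = 5000.0,
    n_face_points: int = 9,
) -> list[DetectorSpec]:
    """The eight compass detectors at azimuths 0, 45, ..., 315 degrees."""
    anchor = (extent_xy_um[0] / 2.0, extent_xy_um[1] / 2.0)
    return [
        DetectorSpec(
            name=name,
            azimuth_deg=az,
            elevation_deg=elevation_deg,
            distance_um=distance_um,
            face_side_um=face_side_um,
            n_face_points=n_face_points,
            anchor_xy=anchor,
        )
        for name, az in COMPASS_AZIMUTHS.items()
    ]
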