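"""Voxelized sample representation shared by the phantom generator and
the inverse reconstruction.

Conventions (package-wide): arrays are indexed (z, y, x), 0-based;
pixel (y=0, x=0) is the North-West corner and x increases East, y
increases South; the support plane is z=0 and the beam travels in -z
(enters at the top of the grid).  Lengths are micrometres, densities
g/cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import constants as xc

__all__ = ["VoxelGrid"]


@dataclass
class VoxelGrid:
    """3D occupancy with per-voxel density and elemental mass fractions.

    Occupied voxels must carry fractions summing to 1 and density > 0;
    empty voxels carry zero density.  Occupied columns are contiguous
    along z (the sample has no interleaving vertical gaps).
    """

    voxel_size: float  # um, isotropic
    occupancy: np.ndarray  # (nz, ny, nx) bool
    density: np.ndarray  # (nz, ny, nx) g/cm^3
    fractions: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    # ------------------------------------------------------------------
    @classmethod
    def empty(cls, shape_zyx, voxel_size=1.0, elements=()):
        nz, ny, nx = shape_zyx
        return cls(
            voxel_size=float(voxel_size),
            occupancy=np.zeros((nz, ny, nx), dtype=bool),
            density=np.zeros((nz, ny, nx)),
            fractions={s: np.zeros((nz, ny, nx)) for s in elements},
        )

    @classmethod
    def from_columns(
        cls,
        thickness_vox: np.ndarray,
        offsets_vox: np.ndarray | None,
        nz: int,
        voxel_size: float,
        density: float | np.ndarray,
        fractions_2d: Mapping[str, np.ndarray],
    ) -> "VoxelGrid":
        """Build a column-wise grid: pixel (y, x) occupies z in
        [offset, offset + thickness), composition constant along z."""
        t = np.asarray(thickness_vox, dtype=np.int64)
        o = np.zeros_like(t) if offsets_vox is None else np.asarray(offsets_vox, np.int64)
        if np.any((o < 0) | (o + t > nz)):
            raise ValueError("column extends outside the grid")
        ny, nx = t.shape
        g = cls.empty((nz, ny, nx), voxel_size, fractions_2d.keys())
        z = np.arange(nz)[:, None, None]
        occ = (z >= o[None]) & (z < (o + t)[None])
        g.occupancy = occ
        g.density = np.where(occ, np.broadcast_to(density, (ny, nx))[None], 0.0).astype(float)
        for s, w in fractions_2d.items():
            g.fractions[s] = np.where(occ, np.asarray(w)[None], 0.0)
        return g

    # ------------------------------------------------------------------
    def thickness_map(self) -> np.ndarray:
        """Per-pixel occupied thickness along the beam axis, um."""
        return self.occupancy.sum(axis=0) * self.voxel_size

    def offsets_map(self) -> np.ndarray:
        """Per-pixel lowest occupied z index (0 where the column is empty)."""
        occ = self.occupancy
        any_ = occ.any(axis=0)
        first = occ.argmax(axis=0)
        return np.where(any_, first, 0)

    def volume(self) -> float:
        """Occupied volume, um^3."""
        return float(self.occupancy.sum()) * self.voxel_size**3

    def footprint(self) -> np.ndarray:
        return self.occupancy.any(axis=0)

    # ------------------------------------------------------------------
    def mu_rho(self, E_eV: float) -> np.ndarray:
        """Per-voxel linear attenuation mu_s(E) * rho in 1/um."""
        out = np.zeros(self.shape)
        for sym, w in self.fractions.items():
            out += w * xc.get_element(sym).mu(E_eV)
        return out * self.density * 1e-4  # cm^2/g * g/cm^3 -> 1/cm -> 1/um

    def validate(self, require_support: bool = False) -> None:
        occ = self.occupancy
        if np.any(self.density[occ] <= 0):
            raise ValueError("occupied voxels must have positive density")
        if np.any(self.density[~occ] != 0):
            raise ValueError("empty voxels must have zero density")
        if self.fractions:
            tot = sum(w for w in self.fractions.values())
            if not np.allclose(tot[occ], 1.0, atol=1e-9):
                raise ValueError("occupied-voxel fractions must sum to 1")
        # columns contiguous along z
        count = occ.sum(axis=0)
        first = self.offsets_map()
        z = np.arange(self.shape[0])[:, None, None]
        expect = (z >= first[None]) & (z < (first + count)[None])
        if np.any(expect != occ):
            raise ValueError("occupied columns must be contiguous along z")
        if require_support and np.any(first[count > 0] != 0):
            raise ValueError("columns must rest on the support plane")
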