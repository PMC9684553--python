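"""Synthetic voxelized test samples.

The canonical sample emulates three hemispherical cells of radii 6, 9
and 12 um resting flat on the support plane, with a LoVo-like (human
colon carcinoma) elemental makeup: 61% C, 17% N, 16% O by mass at an
average density of 1.25 g/cm^3.  The remaining 6% is assigned to a
non-fluorescing hydrogen balance so fractions sum to 1; it contributes
to the mixture attenuation but emits no tracked line.  Three 2-um Mg
hot spots (4% Mg, other fractions rescaled) are placed one per cell.

Hemisphere centers are calibrated once so that the union footprint of
the three cells is exactly 778 pixels on the canonical 40x40x14 grid at
1 um voxels, with the largest cell facing the other two; the calibrated
coordinates are frozen below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import VoxelGrid

__all__ = ["PhantomSpec", "build_phantom", "canonical_spec", "LOVO_FRACTIONS"]

LOVO_FRACTIONS = {"C": 0.61, "N": 0.17, "O": 0.16, "H": 0.06}
LOVO_DENSITY = 1.25  # g/cm^3

# frozen calibrated placement (x, y, radius) in um on the 40x40 grid:
# union footprint = 778 px with voxel-center-in-sphere occupancy
_CANONICAL_CELLS = (
    (13.481, 10.736, 9.0),
    (26.689, 10.736, 6.0),
    (23.519, 26.264, 12.0),
)
_MG_ROI_RADIUS = 2.0
_MG_FRACTION = 0.04
# Mg hot spots sit off-center (0.6 r radially outward from the sample
# centroid): contaminant ROIs on the very thickest column would make the
# absorption-scale anchor pixel Mg-enhanced, which the thickness
# retrieval statistics of the emulated study exclude.
_MG_OFFSET_FRAC = 0.6


@dataclass
class PhantomSpec:
    """Geometry + composition recipe for :func:`build_phantom`.

    ``hemispheres`` are (center_x, center_y, radius) in um, resting on
    the support plane z=0 (flat bottom).  ``mg_rois`` are full-column
    disks (center_x, center_y, radius, mg_fraction); inside them the
    base fractions are rescaled by (1 - mg_fraction) so every region
    still sums to 1.
    """

    grid_shape: tuple[int, int, int]  # (nx, ny, nz)
    voxel_size: float = 1.0  # um
    hemispheres: tuple = ()
    base_fractions: dict = field(default_factory=lambda: dict(LOVO_FRACTIONS))
    density: float = LOVO_DENSITY
    mg_rois: tuple = ()

    def validate(self) -> None:
        nx, ny, nz = self.grid_shape
        vs = self.voxel_size
        tot = sum(self.base_fractions.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError("base fractions must sum to 1")
        for cx, cy, r in self.hemispheres:
            if r <= 0:
                raise ValueError("hemisphere radius must be positive")
            if (cx - r < 0 or cx + r > nx * vs or cy - r < 0 or cy + r > ny * vs
                    or r > nz * vs):
                raise ValueError(f"hemisphere ({cx}, {cy}, r={r}) outside the grid")


def canonical_spec(upscale: float = 1.0, voxel_size: float = 1.0) -> PhantomSpec:
    """The frozen three-cell sample; ``upscale`` linearly scales every
    length (the 2.5x variant lives in a 100x100x100 um^3 grid)."""
    u = float(upscale)
    if u == 1.0:
        extent = (40.0, 40.0, 14.0)
    else:
        extent = (40.0 * u, 40.0 * u, 14.0 * u)
        if u == 2.5:
            extent = (100.0, 100.0, 100.0)
    shape = tuple(int(round(e / voxel_size)) for e in extent)
    cells = tuple((cx * u, cy * u, r * u) for cx, cy, r in _CANONICAL_CELLS)
    gx = sum(c[0] for c in _CANONICAL_CELLS) / 3.0
    gy = sum(c[1] for c in _CANONICAL_CELLS) / 3.0
    rois = []
    for cx, cy, r in _CANONICAL_CELLS:
        dx, dy = cx - gx, cy - gy
        norm = (dx * dx + dy * dy) ** 0.5
        ox = cx + _MG_OFFSET_FRAC * r * dx / norm
        oy = cy + _MG_OFFSET_FRAC * r * dy / norm
        rois.append((ox * u, oy * u, _MG_ROI_RADIUS * u, _MG_FRACTION))
    rois = tuple(rois)
    return PhantomSpec(
        grid_shape=shape, voxel_size=voxel_size, hemispheres=cells, mg_rois=rois
    )


def build_phantom(spec: PhantomSpec) -> VoxelGrid:
    """Voxelize the spec: a voxel is occupied iff its center lies inside
    at least one hemisphere; composition is the base mixture except in
    Mg ROIs; density is constant on the sample."""
    spec.validate()
    nx, ny, nz = spec.grid_shape
    vs = spec.voxel_size
    elements = sorted(set(spec.base_fractions) | ({"Mg"} if spec.mg_rois else set()))
    g = VoxelGrid.empty((nz, ny, nx), vs, elements)

    x = (np.arange(nx) + 0.5) * vs
    y = (np.arange(ny) + 0.5) * vs
    z = (np.arange(nz) + 0.5) * vs
    X = x[None, None, :]
    Y = y[None, :, None]
    Z = z[:, None, None]
    occ = np.zeros((nz, ny, nx), dtype=bool)
    for cx, cy, r in spec.hemispheres:
        occ |= (X - cx) ** 2 + (Y - cy) ** 2 + Z**2 < r * r
    g.occupancy = occ
    g.density = np.where(occ, spec.density, 0.0)

    w2d = {s: np.full((ny, nx), w) for s, w in spec.base_fractions.items()}
    if spec.mg_rois:
        w2d.setdefault("Mg", np.zeros((ny, nx)))
        for cx, cy, r, wmg in spec.mg_rois:
            disk = (x[None, :] - cx) ** 2 + (y[:, None] - cy) ** 2 < r * r
            for s in spec.base_fractions:
                w2d[s] = np.where(disk, w2d[s] * (1.0 - wmg), w2d[s])
            w2d["Mg"] = np.where(disk, wmg, w2d["Mg"])
    for s in elements:
        g.fractions[s] = np.where(occ, w2d.get(s, 0.0)[None], 0.0)
    g.validate(require_support=True)
    return g
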