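"""Fundamental-parameter quantification.

Relates recorded line counts to element masses per pixel,

    m_j = C_i S / (I0 Y_ij(E0, E_i) tau_j(E0) K_FP),

with C_i the cumulative counts of line i, S the pixel area and K_FP
the closed-form absorption correction for a uniform column of
thickness h,

    K_FP = (1 - exp(-x)) / x,
    x = rho h (mu_s(E0) cosec(theta) + mu_s(E_i) <cosec(phi)>_alpha).

The first pass discards K_FP (sets it to 1), which yields biased mass
fractions; the bias is what the topography reconstruction is robust
against and what the later 3D correction removes.

Counts are pooled across all detectors, with the per-detector solid
angle fractions summed inside Y_ij accordingly; the mean exit-path
cosecant <cosec(phi)> is the solid-angle-weighted mean over detectors
of the per-detector face-target mean.
"""

from __future__ import annotations

import numpy as np

from . import constants as xc
from .forward import BeamConfig, XRFMapSet, line_key
from .geometry import DetectorSpec

__all__ = [
    "k_fp",
    "element_mass",
    "mass_fractions",
    "mu_maps",
    "quantify",
]


def k_fp(h_um, rho, mu0, mui, cosec_theta: float = 1.0, mean_cosec_phi: float = 1.0):
    """Closed-form uniform-column absorption factor in (0, 1].

    ``h_um`` thickness (um), ``rho`` density (g/cm^3), ``mu0``/``mui``
    mass attenuation at the incident/line energy (cm^2/g).  Returns 1
    in the thin-sample limit x -> 0 (series value).
    """
    h_um = np.asarray(h_um, dtype=float)
    if np.any(h_um < 0) or np.any(np.asarray(rho) < 0):
        raise ValueError("h and rho must be nonnegative")
    x = np.asarray(rho) * (h_um * 1e-4) * (mu0 * cosec_theta + mui * mean_cosec_phi)
    small = np.abs(x) < 1e-8
    safe = np.where(small, 1.0, x)
    out = np.where(small, 1.0 - x / 2.0, -np.expm1(-safe) / safe)
    return float(out) if out.ndim == 0 else out


def pooled_yield(detectors: list[DetectorSpec], element: str, line: str = "K-alpha") -> float:
    """Y_ij summed across detectors (solid angles pooled)."""
    ln = xc.get_element(element).line(line)
    omega = sum(d.solid_angle_fraction for d in detectors)
    return xc.yield_factor(ln, 1.0) * omega


def mean_cosec_phi_pooled(detectors: list[DetectorSpec], pixel_xy) -> float:
    """Solid-angle-weighted mean exit cosecant across detectors."""
    w = np.array([d.solid_angle_fraction for d in detectors])
    c = np.array([d.mean_cosec_phi(pixel_xy) for d in detectors])
    return float((w * c).sum() / w.sum())


def element_mass(counts, pixel_area_um2: float, beam: BeamConfig,
                 element: str, yield_pooled: float, kfp=1.0):
    """Invert the FP relation to grams per pixel; ``kfp`` omitted (=1)
    reproduces the biased first pass."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    tau0 = xc.get_element(element).tau(beam.E0_eV)
    denom = beam.I0 * yield_pooled * tau0 * np.asarray(kfp, dtype=float)
    if np.any(denom <= 0):
        raise ValueError("zero denominator in the FP mass relation")
    s_cm2 = pixel_area_um2 * 1e-8
    out = counts * s_cm2 / denom
    return float(out) if out.ndim == 0 else out


def mass_fractions(masses: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Normalize per-element masses to fractions; all-zero pixels are
    flagged with NaN."""
    total = sum(np.asarray(m, dtype=float) for m in masses.values())
    if np.ndim(total) == 0:
        if total <= 0:
            raise ValueError("all-zero masses: fractions undefined")
        return {s: float(m) / float(total) for s, m in masses.items()}
    safe = np.where(total > 0, total, 1.0)
    return {
        s: np.where(total > 0, np.asarray(m, dtype=float) / safe, np.nan)
        for s, m in masses.items()
    }


def mu_maps(fractions: dict[str, np.ndarray], energies) -> dict[float, np.ndarray]:
    """Pixelwise mixture-rule mu_s at each requested energy (cm^2/g).

    ``fractions`` are per-pixel maps that sum to 1 on sample pixels
    (NaN elsewhere is propagated)."""
    tot = sum(np.nan_to_num(w) for w in fractions.values())
    valid = np.isfinite(next(iter(fractions.values())))
    if np.any(np.abs(tot[valid] - 1.0) > 1e-6):
        raise ValueError("fraction maps must sum to 1 on sample pixels")
    out = {}
    for e in energies:
        acc = np.zeros_like(tot)
        for sym, w in fractions.items():
            acc = acc + np.nan_to_num(w) * xc.get_element(sym).mu(float(e))
        out[float(e)] = np.where(valid, acc, np.nan)
    return out


def quantify(
    mapset: XRFMapSet,
    detectors: list[DetectorSpec],
    beam: BeamConfig,
    elements: list[str],
    pixel_area_um2: float = 1.0,
    kfp_maps: dict[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Per-pixel mass-fraction maps from detector-pooled count maps.

    With ``kfp_maps`` None this is the biased first pass (K_FP = 1);
    otherwise supply one K_FP map per element.
    """
    masses = {}
    for el in elements:
        key = line_key(el, "K-alpha")
        counts = mapset.summed(key)
        y = pooled_yield(detectors, el)
        kfp_el = 1.0 if kfp_maps is None else kfp_maps[el]
        masses[el] = element_mass(counts, pixel_area_um2, beam, el, y, kfp_el)
    return mass_fractions(masses)
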