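"""Iterative thickness-map (z-map) retrieval from an STXM scan.

Beer-Lambert inversion of a single-energy transmission map is
under-determined: T = exp(-mu_s rho z) mixes thickness and density.
The procedure anchors the scale by assigning the maximum expected
thickness h_max to the most absorbing pixel(s) and an initially
constant mu_s(E0) rho to every pixel, then iteratively re-factorizes
pixels whose thickness changes too abruptly against their neighbors:
their thickness is replaced by the neighbor mean and their mu_s rho is
recomputed from the STXM so the product mu_s rho z always reproduces
the measured transmission exactly.

The abruptness threshold (the sample-average rate of change) is frozen
from the initial map: iterating against a per-iteration mean can never
reach an empty flag set (some pixels always exceed the mean) and keeps
smoothing away real relief, whereas the frozen threshold makes the
update contractive and idempotent at convergence.  Neighbor statistics
are taken over sample pixels only (the 8-neighborhood by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ZMapState", "derive_zmap"]

BACKGROUND_T = 0.999  # pixels more transmissive than this are empty


@dataclass
class ZMapState:
    """Result of the iterative retrieval."""

    z: np.ndarray          # thickness, um
    mu_rho: np.ndarray     # mu_s(E0) * rho, 1/um
    footprint: np.ndarray  # sample-pixel mask
    rho_avg: float
    iterations_run: int = 0
    threshold_history: list = field(default_factory=list)


def _neighbor_stats(z, footprint, eight: bool):
    """Per-pixel max |dz| to footprint neighbors and the neighbor mean."""
    ny, nx = z.shape
    shifts = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if eight:
        shifts += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    maxdiff = np.zeros_like(z)
    nb_sum = np.zeros_like(z)
    nb_cnt = np.zeros_like(z)
    for dy, dx in shifts:
        zs = np.full_like(z, np.nan)
        fs = np.zeros_like(footprint)
        ys0, ys1 = max(0, -dy), min(ny, ny - dy)
        xs0, xs1 = max(0, -dx), min(nx, nx - dx)
        zs[ys0:ys1, xs0:xs1] = z[ys0 + dy:ys1 + dy, xs0 + dx:xs1 + dx]
        fs[ys0:ys1, xs0:xs1] = footprint[ys0 + dy:ys1 + dy, xs0 + dx:xs1 + dx]
        valid = fs & footprint
        d = np.where(valid, np.abs(z - zs), 0.0)
        maxdiff = np.maximum(maxdiff, d)
        nb_sum += np.where(valid, zs, 0.0)
        nb_cnt += valid
    return maxdiff, nb_sum, nb_cnt


def derive_zmap(
    stxm: np.ndarray,
    rho_avg: float,
    h_max: float,
    n_iter: int = 1000,
    eight_neighbors: bool = True,
) -> ZMapState:
    """Retrieve thickness and mu_s(E0) rho maps from one STXM scan.

    Parameters: ``stxm`` transmission in (0, 1]; ``rho_avg`` the
    average sample density (g/cm^3, recorded for downstream density
    estimates); ``h_max`` the maximum expected thickness (um);
    ``n_iter`` the number of smoothing iterations (an early exit fires
    when no pixel exceeds the slope threshold).
    """
    stxm = np.asarray(stxm, dtype=float)
    if np.any(stxm <= 0) or np.any(stxm > 1):
        raise ValueError("STXM transmission must lie in (0, 1]")
    if h_max <= 0 or n_iter < 1:
        raise ValueError("h_max must be positive and n_iter >= 1")
    footprint = stxm <= BACKGROUND_T
    state = ZMapState(
        z=np.zeros_like(stxm), mu_rho=np.zeros_like(stxm),
        footprint=footprint, rho_avg=rho_avg,
    )
    if not footprint.any():
        warnings.warn("all-background STXM: returning an empty z-map", stacklevel=2)
        return state

    neg_log_t = -np.log(stxm, where=footprint, out=np.zeros_like(stxm))
    t_min = stxm[footprint].min()
    mu_rho0 = -np.log(t_min) / h_max
    z = np.where(footprint, neg_log_t / mu_rho0, 0.0)
    z[footprint & (stxm <= t_min + 1e-9)] = h_max  # ties share h_max
    mu_rho = np.where(footprint, neg_log_t / np.where(z > 0, z, 1.0), 0.0)

    threshold = None
    for it in range(n_iter):
        maxdiff, nb_sum, nb_cnt = _neighbor_stats(z, footprint, eight_neighbors)
        has_nb = footprint & (nb_cnt > 0)
        if not has_nb.any():
            break
        if threshold is None:
            # the average rate of change of the INITIAL map; freezing it
            # makes the iteration contractive (with a per-iteration
            # threshold half the sample always exceeds the mean and the
            # smoothing never stops eating real structure)
            threshold = float(maxdiff[has_nb].mean())
        state.threshold_history.append(threshold)
        flags = has_nb & (maxdiff > threshold)
        if not flags.any():
            state.iterations_run = it
            break
        z_new = nb_sum[flags] / nb_cnt[flags]
        z = z.copy()
        z[flags] = z_new
        mu_rho = np.where(footprint & (z > 0), neg_log_t / np.where(z > 0, z, 1.0), 0.0)
        state.iterations_run = it + 1

    state.z = z
    state.mu_rho = mu_rho
    return state
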