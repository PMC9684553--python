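"""Numba ray-tracing kernels.

Two grid representations are traced:

* a general 3D per-voxel field (exact incremental voxel walking, used
  for forward simulation of arbitrary grids and as the reference path
  integral), and
* a column-interval representation (per-pixel bottom/top and a
  column-constant attenuation value), used in the hot loops of the
  inverse reconstruction where sample columns are rigid vertical
  segments.  A 2D traversal with analytic z-interval overlap is exact
  for this representation and much cheaper.

All lengths in um; attenuation values are linear coefficients in 1/um.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "line_integral_3d",
    "k_matrix_3d",
    "column_line_integral",
    "build_crossings",
    "score_candidates",
]

_EPS = 1e-9


@njit(cache=True)
def _clip_to_box(p0, p1, ext):
    """Return (t_enter, t_exit) of segment p0->p1 against [0,ext]^3."""
    t0, t1 = 0.0, 1.0
    for a in range(3):
        d = p1[a] - p0[a]
        if abs(d) < 1e-30:
            if p0[a] < 0.0 or p0[a] > ext[a]:
                return 1.0, 0.0
        else:
            ta = (0.0 - p0[a]) / d
            tb = (ext[a] - p0[a]) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    return t0, t1


@njit(cache=True)
def line_integral_3d(field, voxel_size, p0, p1):
    """Integral of a per-voxel field along segment p0 -> p1 (exact
    chord lengths, Amanatides-Woo voxel walking).  field is (nz,ny,nx);
    points are (x, y, z) in um."""
    nz, ny, nx = field.shape
    ext = np.array([nx * voxel_size, ny * voxel_size, nz * voxel_size])
    t0, t1 = _clip_to_box(p0, p1, ext)
    if t1 <= t0:
        return 0.0
    dx = p1[0] - p0[0]
    dy = p1[1] - p0[1]
    dz = p1[2] - p0[2]
    seg_len = np.sqrt(dx * dx + dy * dy + dz * dz)
    t = t0 + _EPS
    # current voxel
    ix = int((p0[0] + t * dx) / voxel_size)
    iy = int((p0[1] + t * dy) / voxel_size)
    iz = int((p0[2] + t * dz) / voxel_size)
    if ix < 0: ix = 0
    if iy < 0: iy = 0
    if iz < 0: iz = 0
    if ix > nx - 1: ix = nx - 1
    if iy > ny - 1: iy = ny - 1
    if iz > nz - 1: iz = nz - 1
    step_x = 1 if dx > 0 else -1
    step_y = 1 if dy > 0 else -1
    step_z = 1 if dz > 0 else -1
    big = 1e30
    tmax_x = ((ix + (step_x > 0)) * voxel_size - p0[0]) / dx if dx != 0.0 else big
    tmax_y = ((iy + (step_y > 0)) * voxel_size - p0[1]) / dy if dy != 0.0 else big
    tmax_z = ((iz + (step_z > 0)) * voxel_size - p0[2]) / dz if dz != 0.0 else big
    tdel_x = abs(voxel_size / dx) if dx != 0.0 else big
    tdel_y = abs(voxel_size / dy) if dy != 0.0 else big
    tdel_z = abs(voxel_size / dz) if dz != 0.0 else big
    acc = 0.0
    t_cur = t0
    while t_cur < t1:
        t_next = tmax_x
        axis = 0
        if tmax_y < t_next:
            t_next = tmax_y
            axis = 1
        if tmax_z < t_next:
            t_next = tmax_z
            axis = 2
        t_stop = t_next if t_next < t1 else t1
        acc += field[iz, iy, ix] * (t_stop - t_cur) * seg_len
        t_cur = t_stop
        if t_next >= t1:
            break
        if axis == 0:
            ix += step_x
            tmax_x += tdel_x
            if ix < 0 or ix >= nx:
                break
        elif axis == 1:
            iy += step_y
            tmax_y += tdel_y
            if iy < 0 or iy >= ny:
                break
        else:
            iz += step_z
            tmax_z += tdel_z
            if iz < 0 or iz >= nz:
                break
    return acc


@njit(cache=True)
def k_matrix_3d(murho, occupancy, voxel_size, targets):
    """Mean exit-path transmission per voxel toward one detector.

    For every occupied voxel, traces from the voxel center to each face
    target and averages exp(-optical depth); empty voxels get K = 1.
    """
    nz, ny, nx = murho.shape
    n_t = targets.shape[0]
    out = np.ones((nz, ny, nx))
    for iz in range(nz):
        for iy in range(ny):
            for ix in range(nx):
                if not occupancy[iz, iy, ix]:
                    continue
                p0 = np.array([(ix + 0.5) * voxel_size,
                               (iy + 0.5) * voxel_size,
                               (iz + 0.5) * voxel_size])
                acc = 0.0
                for it in range(n_t):
                    od = line_integral_3d(murho, voxel_size, p0, targets[it])
                    acc += np.exp(-od)
                out[iz, iy, ix] = acc / n_t
    return out


@njit(cache=True)
def column_line_integral(zbot, ztop, value, voxel_size, p0, p1):
    """Integral of a column-constant field along p0 -> p1 through a
    column-interval grid: pixel (iy, ix) is filled with ``value`` for
    z in [zbot, ztop).  Exact for ascending, non-horizontal rays."""
    ny, nx = zbot.shape
    ext_x = nx * voxel_size
    ext_y = ny * voxel_size
    dx = p1[0] - p0[0]
    dy = p1[1] - p0[1]
    dz = p1[2] - p0[2]
    seg_len = np.sqrt(dx * dx + dy * dy + dz * dz)
    # clip against xy extents only (z handled analytically per column)
    t0, t1 = 0.0, 1.0
    for a in range(2):
        p = p0[a]
        d = dx if a == 0 else dy
        e = ext_x if a == 0 else ext_y
        if abs(d) < 1e-30:
            if p < 0.0 or p > e:
                return 0.0
        else:
            ta = (0.0 - p) / d
            tb = (e - p) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    if t1 <= t0:
        return 0.0
    t = t0 + _EPS
    ix = int((p0[0] + t * dx) / voxel_size)
    iy = int((p0[1] + t * dy) / voxel_size)
    if ix < 0: ix = 0
    if iy < 0: iy = 0
    if ix > nx - 1: ix = nx - 1
    if iy > ny - 1: iy = ny - 1
    step_x = 1 if dx > 0 else -1
    step_y = 1 if dy > 0 else -1
    big = 1e30
    tmax_x = ((ix + (step_x > 0)) * voxel_size - p0[0]) / dx if dx != 0.0 else big
    tmax_y = ((iy + (step_y > 0)) * voxel_size - p0[1]) / dy if dy != 0.0 else big
    tdel_x = abs(voxel_size / dx) if dx != 0.0 else big
    tdel_y = abs(voxel_size / dy) if dy != 0.0 else big
    acc = 0.0
    t_cur = t0
    while t_cur < t1:
        t_next = tmax_x
        axis = 0
        if tmax_y < t_next:
            t_next = tmax_y
            axis = 1
        t_stop = t_next if t_next < t1 else t1
        v = value[iy, ix]
        if v != 0.0:
            za = p0[2] + t_cur * dz
            zb = p0[2] + t_stop * dz
            if za > zb:
                za, zb = zb, za
            lo = za if za > zbot[iy, ix] else zbot[iy, ix]
            hi = zb if zb < ztop[iy, ix] else ztop[iy, ix]
            if hi > lo:
                if zb > za:
                    acc += v * seg_len * (t_stop - t_cur) * (hi - lo) / (zb - za)
                else:
                    acc += v * seg_len * (t_stop - t_cur)
        t_cur = t_stop
        if t_next >= t1:
            break
        if axis == 0:
            ix += step_x
            tmax_x += tdel_x
            if ix < 0 or ix >= nx:
                break
        else:
            iy += step_y
            tmax_y += tdel_y
            if iy < 0 or iy >= ny:
                break
    return acc


# ----------------------------------------------------------------------
# Candidate-scoring machinery for the inverse reconstruction.
#
# A region of interest holds M member pixels whose rigid columns may be
# shifted vertically.  Ray geometry is precomputed once per region with
# all member columns at offset zero; a candidate shifts every ray cast
# from a member column upward together with the column (parallel-shift:
# exact up to the source-to-face parallax, < 0.1% at tens of mm detector
# distance).  Each ray is stored as a list of pixel crossings carrying
# the ray's z-interval inside that pixel cell and the cell's
# attenuation-weighted length; overlap with the (shifted) column
# interval is then a few flops per crossing.
# ----------------------------------------------------------------------


@njit(cache=True)
def build_crossings(member_map, ctx_zbot, ctx_h, member_h, mu_rho_px,
                    voxel_size, p0s, p1s, max_cross):
    """Precompute per-ray pixel crossings.

    member_map: (ny,nx) int32, index of the ROI member owning the pixel
        or -1 (context / empty).
    ctx_zbot, ctx_h: context column bottom and height per pixel (um);
        pixels being optimized still carry their height in member_h.
    mu_rho_px: per-pixel linear attenuation at the traced line energy.
    Returns (ray_ptr, c_member, c_zbot, c_h, c_zlo, c_zhi, c_w).
    """
    nr = p0s.shape[0]
    ny, nx = member_map.shape
    ext_x = nx * voxel_size
    ext_y = ny * voxel_size
    ray_ptr = np.zeros(nr + 1, dtype=np.int64)
    c_member = np.empty(nr * max_cross, dtype=np.int32)
    c_zbot = np.empty(nr * max_cross)
    c_h = np.empty(nr * max_cross)
    c_zlo = np.empty(nr * max_cross)
    c_zhi = np.empty(nr * max_cross)
    c_w = np.empty(nr * max_cross)
    n = 0
    for r in range(nr):
        p0 = p0s[r]
        p1 = p1s[r]
        dx = p1[0] - p0[0]
        dy = p1[1] - p0[1]
        dz = p1[2] - p0[2]
        seg_len = np.sqrt(dx * dx + dy * dy + dz * dz)
        t0, t1 = 0.0, 1.0
        ok = True
        for a in range(2):
            p = p0[a]
            d = dx if a == 0 else dy
            e = ext_x if a == 0 else ext_y
            if abs(d) < 1e-30:
                if p < 0.0 or p > e:
                    ok = False
            else:
                ta = (0.0 - p) / d
                tb = (e - p) / d
                if ta > tb:
                    ta, tb = tb, ta
                if ta > t0:
                    t0 = ta
                if tb < t1:
                    t1 = tb
        if ok and t1 > t0:
            t = t0 + _EPS
            ix = int((p0[0] + t * dx) / voxel_size)
            iy = int((p0[1] + t * dy) / voxel_size)
            if ix < 0: ix = 0
            if iy < 0: iy = 0
            if ix > nx - 1: ix = nx - 1
            if iy > ny - 1: iy = ny - 1
            step_x = 1 if dx > 0 else -1
            step_y = 1 if dy > 0 else -1
            big = 1e30
            tmax_x = ((ix + (step_x > 0)) * voxel_size - p0[0]) / dx if dx != 0.0 else big
            tmax_y = ((iy + (step_y > 0)) * voxel_size - p0[1]) / dy if dy != 0.0 else big
            tdel_x = abs(voxel_size / dx) if dx != 0.0 else big
            tdel_y = abs(voxel_size / dy) if dy != 0.0 else big
            t_cur = t0
            while t_cur < t1:
                t_next = tmax_x
                axis = 0
                if tmax_y < t_next:
                    t_next = tmax_y
                    axis = 1
                t_stop = t_next if t_next < t1 else t1
                m = member_map[iy, ix]
                h = member_h[m] if m >= 0 else ctx_h[iy, ix]
                if h > 0.0 and mu_rho_px[iy, ix] > 0.0:
                    za = p0[2] + t_cur * dz
                    zb = p0[2] + t_stop * dz
                    if za > zb:
                        za, zb = zb, za
                    c_member[n] = m
                    c_zbot[n] = 0.0 if m >= 0 else ctx_zbot[iy, ix]
                    c_h[n] = h
                    c_zlo[n] = za
                    c_zhi[n] = zb
                    if zb > za:
                        c_w[n] = mu_rho_px[iy, ix] * seg_len * (t_stop - t_cur) / (zb - za)
                    else:
                        c_w[n] = 0.0
                    n += 1
                t_cur = t_stop
                if t_next >= t1:
                    break
                if axis == 0:
                    ix += step_x
                    tmax_x += tdel_x
                    if ix < 0 or ix >= nx:
                        break
                else:
                    iy += step_y
                    tmax_y += tdel_y
                    if iy < 0 or iy >= ny:
                        break
        ray_ptr[r + 1] = n
    return ray_ptr, c_member[:n], c_zbot[:n], c_h[:n], c_zlo[:n], c_zhi[:n], c_w[:n]


@njit(cache=True)
def context_od_table(ray_ptr, c_zbot, c_h, c_zlo, c_zhi, c_w, n_off, voxel_size):
    """Optical depth through the fixed context columns per ray, for
    every possible vertical shift of the ray (= the source column's
    candidate offset).  Shape (n_rays, n_off)."""
    nr = ray_ptr.shape[0] - 1
    out = np.zeros((nr, n_off))
    for r in range(nr):
        for o in range(n_off):
            shift = o * voxel_size
            od = 0.0
            for q in range(ray_ptr[r], ray_ptr[r + 1]):
                lo = c_zlo[q] + shift
                hi = c_zhi[q] + shift
                if c_zbot[q] > lo:
                    lo = c_zbot[q]
                top = c_zbot[q] + c_h[q]
                if top < hi:
                    hi = top
                if hi > lo:
                    od += c_w[q] * (hi - lo)
            out[r, o] = od
    return out


@njit(cache=True)
def score_candidates(cand_offsets, src_member, em, n_face_points, voxel_size,
                     ray_ptr, m_member, m_h, m_zlo, m_zhi, m_w, ctx_od,
                     target, n_members):
    """L1 score of every candidate against the target counts.

    cand_offsets: (n_cand, n_members) integer voxel offsets.
    src_member/em: per source voxel, owning member and its expected
        emitted counts (detector yield already applied).
    Rays of source s are indices s*n_face_points ... (s+1)*n_face_points-1;
    ray_ptr indexes the member-cell crossings only, the context part is
    looked up in ctx_od by (ray, source offset).
    """
    n_cand = cand_offsets.shape[0]
    n_src = src_member.shape[0]
    scores = np.empty(n_cand)
    sim = np.empty(n_members)
    for c in range(n_cand):
        for m in range(n_members):
            sim[m] = 0.0
        for s in range(n_src):
            ms = src_member[s]
            o_self = cand_offsets[c, ms]
            shift = o_self * voxel_size
            acc = 0.0
            for j in range(n_face_points):
                r = s * n_face_points + j
                od = ctx_od[r, o_self]
                for q in range(ray_ptr[r], ray_ptr[r + 1]):
                    zb = m_zlo[q] + shift  # ray z-interval, shifted
                    hi = m_zhi[q] + shift
                    mb = cand_offsets[c, m_member[q]] * voxel_size
                    lo = zb if zb > mb else mb
                    top = mb + m_h[q]
                    if top < hi:
                        hi = top
                    if hi > lo:
                        od += m_w[q] * (hi - lo)
                acc += np.exp(-od)
            sim[ms] += em[s] * acc / n_face_points
        sc = 0.0
        for m in range(n_members):
            d = sim[m] - target[m]
            sc += d if d >= 0.0 else -d
        scores[c] = sc
    return scores
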