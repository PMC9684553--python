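"""Ray-tracing inverse reconstruction of the 3D sample topography.

Each detector sees a different self-absorption imprint of the same
topography.  Per detector the algorithm:

1. expands the retrieved thickness map into support-resting 3D columns
   and computes a coverage map: the sample path length between each
   pixel's column top and the detector face center;
2. picks the least-shielded unresolved pixel as a seed, walks the line
   from the seed away from the detector, and at equally spaced apexes
   opens a conical region of interest (the projected cone of exit
   directions toward the detector face);
3. enumerates every gap-free rigid vertical translation of the
   unresolved member columns (previously fixed members are frozen),
   subsampling equidistantly to at most ``delta`` candidates;
4. scores each candidate by forward-simulating the target line's 2D
   counts at the member pixels and summing |simulated - measured|
   (L1); the lowest score is fixed in 3D and the next region opens.

Detectors are gated per pixel by the oversampling parameter ``ir_os``:
coverage levels are normalized by the pixel's most-shielded detector
and a detector reconstructs the pixel iff its normalized coverage is
<= ir_os (the least-shielded detector always does).  The per-detector
topographies are merged by a weighted average of column offsets with
weights 1 - normalized coverage, so the least-attenuated detectors
dominate.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field as dfield

import numpy as np

from . import constants as xc
from .forward import BeamConfig, XRFMapSet, line_key
from .fp import mu_maps
from .geometry import DetectorSpec
from .grid import VoxelGrid
from .tracing import (
    build_crossings, column_line_integral, context_od_table, score_candidates,
)
from .zmap import ZMapState

__all__ = [
    "IRConfig",
    "DerivedSample",
    "IRResult",
    "coverage_map",
    "select_seed_and_line",
    "conical_roi",
    "enumerate_candidates",
    "reconstruct_detector",
    "merge_topographies",
    "reconstruct",
]


@dataclass(frozen=True)
class IRConfig:
    """Tunables of the inverse reconstruction.

    ir_os in [0, 1] gates which detectors reconstruct which pixels;
    delta >= 1 caps the candidates tested per region; stride (pixels
    between apexes along a seed line) defaults to half the cone
    footprint width at mid-range; seed feeds any stochastic target
    resampling and is recorded in outputs (the search itself is
    deterministic).
    """

    ir_os: float = 0.2
    delta: int = 1000
    stride: int | None = None
    n_face_points: int = 9
    target_lines: tuple = (("C", "K-alpha"),)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.ir_os <= 1.0:
            raise ValueError("ir_os must be in [0, 1]")
        if self.delta < 1:
            raise ValueError("delta must be >= 1")


@dataclass
class DerivedSample:
    """Per-pixel sample description the IR simulates with: thickness in
    voxels plus column-constant attenuation and emission factors derived
    from the z-map and the first-pass FP fractions."""

    voxel_size: float
    nz: int
    t_vox: np.ndarray                 # (ny, nx) int
    mu_rho0: np.ndarray               # mu_s(E0) rho, 1/um
    mu_rho_line: dict                 # line key -> (ny, nx) 1/um
    em_factor: dict                   # line key -> (ny, nx) photons per voxel
                                      # before solid angle and incident attenuation

    @classmethod
    def from_first_pass(
        cls,
        zstate: ZMapState,
        fractions: dict[str, np.ndarray],
        beam: BeamConfig,
        voxel_size: float,
        nz: int,
        lines=(("C", "K-alpha"),),
    ) -> "DerivedSample":
        energies = [beam.E0_eV] + [xc.line_energy(e, l) for e, l in lines]
        mus = mu_maps(fractions, energies)
        mu0 = mus[beam.E0_eV]
        rho_hat = np.where(mu0 > 0, zstate.mu_rho * 1e4 / np.where(mu0 > 0, mu0, 1.0), 0.0)
        rho_hat = np.nan_to_num(rho_hat)
        mu_rho_line = {}
        em_factor = {}
        dz_cm = voxel_size * 1e-4
        for el, ln in lines:
            key = line_key(el, ln)
            e_i = xc.line_energy(el, ln)
            ratio = np.where(mu0 > 0, mus[e_i] / np.where(mu0 > 0, mu0, 1.0), 0.0)
            mu_rho_line[key] = np.nan_to_num(zstate.mu_rho * ratio)
            rec = xc.get_element(el)
            y_geo = xc.yield_factor(rec.line(ln), 1.0)  # omega p J (no solid angle)
            w_el = np.nan_to_num(fractions.get(el, np.zeros_like(mu0)))
            em_factor[key] = (
                w_el * rho_hat * rec.tau(beam.E0_eV) * y_geo * beam.I0 * dz_cm
            )
        t_vox = np.where(
            zstate.footprint, np.maximum(np.round(zstate.z / voxel_size), 1), 0
        ).astype(np.int64)
        t_vox = np.minimum(t_vox, nz)
        return cls(
            voxel_size=voxel_size, nz=nz, t_vox=t_vox,
            mu_rho0=np.nan_to_num(zstate.mu_rho),
            mu_rho_line=mu_rho_line, em_factor=em_factor,
        )


# ----------------------------------------------------------------------
def coverage_map(
    thickness_um: np.ndarray,
    voxel_size: float,
    detector: DetectorSpec,
    offsets_um: np.ndarray | None = None,
) -> np.ndarray:
    """Sample path length (um) between each pixel's column top and the
    detector face center, through the support-resting 3D expansion of
    the thickness map (the pixel's own column does not shield itself)."""
    t = np.asarray(thickness_um, dtype=float)
    ny, nx = t.shape
    zbot = np.zeros_like(t) if offsets_um is None else np.asarray(offsets_um, float)
    ztop = zbot + t
    ones = (t > 0).astype(float)
    face = detector.face_center
    out = np.zeros_like(t)
    for iy, ix in zip(*np.nonzero(t > 0)):
        p0 = np.array([(ix + 0.5) * voxel_size, (iy + 0.5) * voxel_size, ztop[iy, ix]])
        out[iy, ix] = column_line_integral(zbot, ztop, ones, voxel_size, p0, face)
    return out


def select_seed_and_line(
    coverage: np.ndarray,
    eligible: np.ndarray,
    detector: DetectorSpec,
    stride: int,
) -> list[tuple[int, int]]:
    """Least-shielded eligible pixel plus the rasterized line through it
    away from the detector, subsampled every ``stride`` pixels.  Ties on
    coverage resolve to the smallest row-major index."""
    if not eligible.any():
        return []
    cov = np.where(eligible, coverage, np.inf)
    seed_flat = int(np.argmin(cov))  # row-major first on ties
    ny, nx = coverage.shape
    sy, sx = divmod(seed_flat, nx)
    ux, uy = detector.horizontal_dir
    # walk away from the detector in half-pixel steps, dedupe
    line = [(sy, sx)]
    k = 0
    while True:
        k += 1
        px = sx + 0.5 - 0.5 * k * ux
        py = sy + 0.5 - 0.5 * k * uy
        iy, ix = int(np.floor(py)), int(np.floor(px))
        if not (0 <= iy < ny and 0 <= ix < nx):
            break
        if (iy, ix) != line[-1]:
            line.append((iy, ix))
    return line[::stride]


def conical_roi(
    apex: tuple[int, int],
    detector: DetectorSpec,
    shape: tuple[int, int],
) -> list[tuple[int, int]]:
    """Pixels inside the 2D-projected cone of exit directions from the
    apex toward the detector face, apex first, ordered by distance from
    the apex (row-major on ties).  The cone is floored at one pixel of
    lateral half-width so a vanishing face still yields the line of
    pixels toward the detector."""
    ny, nx = shape
    ay, ax = apex
    half_angle = np.arctan(0.5 * detector.face_side_um / detector.distance_um)
    tan_h = np.tan(half_angle)
    ux, uy = detector.horizontal_dir
    ys, xs = np.mgrid[0:ny, 0:nx]
    vx = xs - ax
    vy = ys - ay
    s = vx * ux + vy * uy  # along-axis distance toward the detector
    lat = np.abs(vx * (-uy) + vy * ux)
    inside = (s >= 0) & (lat <= np.maximum(s * tan_h, 0.5))
    members = list(zip(*np.nonzero(inside)))
    members.sort(key=lambda p: ((p[0] - ay) ** 2 + (p[1] - ax) ** 2, p[0], p[1]))
    return members


# ----------------------------------------------------------------------
def _window_sum(prefix, lo, hi):
    """Sum of counts over offsets [lo, hi] from a prefix array."""
    if hi < lo:
        return 0
    return prefix[hi + 1] - prefix[lo]


def enumerate_candidates(
    t_vox: np.ndarray,
    fixed: np.ndarray,
    fixed_offsets: np.ndarray,
    nz: int,
    delta: int,
    linked: np.ndarray | None = None,
) -> np.ndarray | None:
    """All gap-free vertical placements of the member columns, frozen
    members pinned, in lexicographic order; if more than ``delta``
    exist, every ceil(total/delta)-th is taken (equidistant sampling).

    Consecutive members must overlap by at least one voxel level
    wherever ``linked`` is True for the pair (default: every pair);
    callers pass the spatial-adjacency of consecutive ROI members so the
    no-vertical-gap rule binds exactly between adjacent pixels.
    Returns (n_cand, M) offsets, or None when the frozen constraints
    admit no placement.
    """
    t = np.asarray(t_vox, dtype=np.int64)
    m = len(t)
    if np.any(t < 1):
        raise ValueError("member thicknesses must be >= 1 voxel")
    if linked is None:
        linked = np.ones(max(m - 1, 0), dtype=bool)
    ranges = []
    for i in range(m):
        if fixed[i]:
            ranges.append((int(fixed_offsets[i]), int(fixed_offsets[i])))
        else:
            ranges.append((0, int(nz - t[i])))
    # backward DP: cnt[i][o - lo_i] = completions of suffix i.. given offset o
    cnts = [None] * m
    last_lo, last_hi = ranges[-1]
    cnts[m - 1] = np.ones(last_hi - last_lo + 1, dtype=object)
    for i in range(m - 2, -1, -1):
        lo_n, hi_n = ranges[i + 1]
        nxt = cnts[i + 1]
        prefix = np.zeros(len(nxt) + 1, dtype=object)
        prefix[1:] = np.cumsum(nxt)
        lo_i, hi_i = ranges[i]
        cur = np.zeros(hi_i - lo_i + 1, dtype=object)
        for o in range(lo_i, hi_i + 1):
            if linked[i]:
                # overlap >= 1: o' in [o - t[i+1] + 1, o + t[i] - 1]
                a = max(lo_n, o - int(t[i + 1]) + 1)
                b = min(hi_n, o + int(t[i]) - 1)
            else:
                a, b = lo_n, hi_n
            cur[o - lo_i] = _window_sum(prefix, a - lo_n, b - lo_n)
        cnts[i] = cur
    total = int(np.sum(cnts[0]))
    if total == 0:
        return None
    # per-node prefix sums once, then each candidate is unranked by
    # bisection inside the compatibility window (O(M log R) per index)
    prefixes = []
    for i in range(m):
        pre = [0]
        for c in cnts[i]:
            pre.append(pre[-1] + int(c))
        prefixes.append(pre)
    n_take = min(delta, total)
    out = np.empty((n_take, m), dtype=np.int64)
    for row in range(n_take):
        rem = (row * total) // n_take
        prev_o = None
        for i in range(m):
            lo_i, hi_i = ranges[i]
            if prev_o is None or not linked[i - 1]:
                a, b = lo_i, hi_i
            else:
                a = max(lo_i, prev_o - int(t[i]) + 1)
                b = min(hi_i, prev_o + int(t[i - 1]) - 1)
            pre = prefixes[i]
            base = pre[a - lo_i]
            # smallest o in [a, b] with cumulative count > rem
            j = bisect.bisect_right(pre, rem + base, a - lo_i + 1, b - lo_i + 1)
            o = lo_i + j - 1
            rem -= pre[j - 1] - base
            out[row, i] = o
            prev_o = o
    return out


# ----------------------------------------------------------------------
def _roi_score_setup(members, sample: DerivedSample, detector, key):
    """Precompute the per-source emission and ray crossings for one ROI."""
    vs = sample.voxel_size
    m = len(members)
    member_map = np.full(sample.t_vox.shape, -1, dtype=np.int32)
    for i, (y, x) in enumerate(members):
        member_map[y, x] = i
    member_h = np.array([sample.t_vox[y, x] * vs for y, x in members])
    srcs_member = []
    srcs_em = []
    p0s = []
    mu0 = sample.mu_rho0
    emf = sample.em_factor[key]
    omega = detector.solid_angle_fraction
    for i, (y, x) in enumerate(members):
        t = int(sample.t_vox[y, x])
        for k in range(t):
            depth = (t - k - 0.5) * vs  # from the column top, offset-invariant
            srcs_member.append(i)
            srcs_em.append(emf[y, x] * omega * np.exp(-mu0[y, x] * depth))
            p0s.append([(x + 0.5) * vs, (y + 0.5) * vs, (k + 0.5) * vs])
    src_member = np.asarray(srcs_member, dtype=np.int64)
    em = np.asarray(srcs_em)
    p0s = np.asarray(p0s)
    targets = detector.face_targets()
    npts = len(targets)
    nray = len(p0s) * npts
    p0_rays = np.repeat(p0s, npts, axis=0)
    p1_rays = np.tile(targets, (len(p0s), 1))
    return member_map, member_h, src_member, em, p0_rays, p1_rays, nray


def reconstruct_detector(
    target_maps: dict[str, np.ndarray],
    sample: DerivedSample,
    detector: DetectorSpec,
    eligible: np.ndarray,
    config: IRConfig,
    coverage: np.ndarray | None = None,
) -> np.ndarray:
    """Resolve a column-offset map for one detector; pixels outside
    ``eligible`` (or never visited) keep the support-resting placement.
    Deterministic: identical inputs produce identical output."""
    vs = sample.voxel_size
    ny, nx = sample.t_vox.shape
    t_um = sample.t_vox * vs
    if coverage is None:
        coverage = coverage_map(t_um, vs, detector)
    stride = config.stride or default_stride(sample, detector)
    offsets = np.zeros((ny, nx), dtype=np.int64)
    resolved = np.zeros((ny, nx), dtype=bool)
    eligible = eligible & (sample.t_vox > 0)
    keys = [line_key(e, l) for e, l in config.target_lines]

    while True:
        unres = eligible & ~resolved
        if not unres.any():
            break
        apexes = select_seed_and_line(coverage, unres, detector, stride)
        progressed = False
        for apex in apexes:
            roi = [p for p in conical_roi(apex, detector, (ny, nx))
                   if sample.t_vox[p] > 0]
            opt = [eligible[p] and not resolved[p] for p in roi]
            if not any(opt):
                continue
            t_m = np.array([sample.t_vox[p] for p in roi])
            fixed = np.array([not o for o in opt])
            fixed_off = np.array([offsets[p] for p in roi])
            linked = np.array([
                max(abs(roi[i][0] - roi[i + 1][0]), abs(roi[i][1] - roi[i + 1][1])) <= 1
                for i in range(len(roi) - 1)
            ], dtype=bool)
            cands = enumerate_candidates(
                t_m, fixed, fixed_off, sample.nz, config.delta, linked=linked
            )
            if cands is None:
                warnings.warn(
                    f"over-constrained region at apex {apex} for {detector.name}: "
                    "keeping support-resting placement", stacklevel=2
                )
                for p, o in zip(roi, opt):
                    if o:
                        resolved[p] = True
                progressed = True
                continue
            scores = np.zeros(len(cands))
            n_off = int(cands.max()) + 1
            for key in keys:
                setup = _roi_score_setup(roi, sample, detector, key)
                member_map, member_h, src_member, em, p0r, p1r, _ = setup
                ctx_zbot = (offsets * vs).astype(float)
                ctx_h = t_um.astype(float)  # member cells overridden via member_map
                ray_ptr, cm, cz, ch, zlo, zhi, cw = build_crossings(
                    member_map, ctx_zbot, ctx_h,
                    member_h, sample.mu_rho_line[key], vs, p0r, p1r, nx + ny + 4,
                )
                # split: context crossings feed a per-(ray, offset) table,
                # member crossings stay per candidate
                nray = len(ray_ptr) - 1
                ray_of = np.repeat(np.arange(nray), np.diff(ray_ptr))
                is_m = cm >= 0
                ptr_m = np.zeros(nray + 1, dtype=np.int64)
                np.add.at(ptr_m, ray_of[is_m] + 1, 1)
                ptr_m = np.cumsum(ptr_m)
                ptr_c = np.zeros(nray + 1, dtype=np.int64)
                np.add.at(ptr_c, ray_of[~is_m] + 1, 1)
                ptr_c = np.cumsum(ptr_c)
                ctx_od = context_od_table(
                    ptr_c, cz[~is_m], ch[~is_m], zlo[~is_m], zhi[~is_m],
                    cw[~is_m], n_off, vs,
                )
                tgt = np.array([target_maps[key][p] for p in roi])
                scores += score_candidates(
                    cands, src_member, em, detector.n_face_points, vs,
                    ptr_m, cm[is_m], ch[is_m], zlo[is_m], zhi[is_m], cw[is_m],
                    ctx_od, tgt, len(roi),
                )
            best = int(np.argmin(scores))  # first minimum on ties
            for i, p in enumerate(roi):
                offsets[p] = cands[best, i]
                if opt[i]:
                    resolved[p] = True
            progressed = True
        if not progressed:
            # guard against degenerate geometry: resolve the seed in place
            cov = np.where(unres, coverage, np.inf)
            sy, sx = divmod(int(np.argmin(cov)), nx)
            resolved[sy, sx] = True
    return offsets


def default_stride(sample: DerivedSample, detector: DetectorSpec) -> int:
    """The cone footprint width at mid-range, floored at 1 pixel.
    Because every cone extends from its apex to the grid edge toward
    the detector, consecutive regions still share about half their
    members at this stride."""
    ny, nx = sample.t_vox.shape
    mid_range = 0.25 * (nx + ny) * sample.voxel_size
    half_angle = np.arctan(0.5 * detector.face_side_um / detector.distance_um)
    width = 2.0 * mid_range * np.tan(half_angle)
    return max(1, int(round(width / sample.voxel_size)))


# ----------------------------------------------------------------------
def merge_topographies(
    offsets_by_det: dict[str, np.ndarray],
    norm_coverage: dict[str, np.ndarray],
    assigned: dict[str, np.ndarray],
    t_vox: np.ndarray,
    nz: int,
) -> np.ndarray:
    """Weighted-average merge of per-detector column offsets.

    Weights are 1 - normalized coverage (the least-attenuated detectors
    count most), restricted to the detectors that reconstructed the
    pixel and renormalized; equal weights when all vanish.  The merged
    offset is rounded to the nearest voxel; thickness is preserved."""
    ny, nx = t_vox.shape
    merged = np.zeros((ny, nx), dtype=np.int64)
    for iy, ix in zip(*np.nonzero(t_vox > 0)):
        dets = [d for d in offsets_by_det if assigned[d][iy, ix]]
        if not dets:
            continue  # support-resting fallback
        w = np.array([1.0 - norm_coverage[d][iy, ix] for d in dets])
        if w.sum() <= 0:
            w = np.ones(len(dets))
        w = w / w.sum()
        off = np.array([offsets_by_det[d][iy, ix] for d in dets], dtype=float)
        merged[iy, ix] = int(round(float((w * off).sum())))
    return np.clip(merged, 0, np.maximum(nz - t_vox, 0))


@dataclass
class IRResult:
    """Per-detector and merged topographies plus the gating metadata."""

    merged_offsets: np.ndarray
    offsets_by_det: dict
    coverage: dict
    norm_coverage: dict
    assigned: dict
    sample: DerivedSample
    config: IRConfig
    log: dict = dfield(default_factory=dict)

    def occupancy(self, merged: bool = True, detector: str | None = None) -> np.ndarray:
        off = self.merged_offsets if merged else self.offsets_by_det[detector]
        nz = self.sample.nz
        z = np.arange(nz)[:, None, None]
        return (z >= off[None]) & (z < (off + self.sample.t_vox)[None])

    def to_grid(self, density, fractions_2d) -> VoxelGrid:
        return VoxelGrid.from_columns(
            self.sample.t_vox, self.merged_offsets, self.sample.nz,
            self.sample.voxel_size, density, fractions_2d,
        )


def reconstruct(
    mapset: XRFMapSet,
    sample: DerivedSample,
    detectors: list[DetectorSpec],
    config: IRConfig = IRConfig(),
) -> IRResult:
    """Run the full multi-detector inverse reconstruction."""
    vs = sample.voxel_size
    t_um = sample.t_vox * vs
    coverage = {d.name: coverage_map(t_um, vs, d) for d in detectors}
    stack = np.stack([coverage[d.name] for d in detectors])
    covmax = stack.max(axis=0)
    safe = np.where(covmax > 0, covmax, 1.0)
    norm_cov = {d.name: np.where(covmax > 0, coverage[d.name] / safe, 0.0)
                for d in detectors}
    argmin_det = np.argmin(stack, axis=0)
    assigned = {}
    for i, d in enumerate(detectors):
        assigned[d.name] = (norm_cov[d.name] <= config.ir_os) | (argmin_det == i)
        assigned[d.name] &= sample.t_vox > 0
    offsets_by_det = {}
    for d in detectors:
        offsets_by_det[d.name] = reconstruct_detector(
            mapset.maps[d.name], sample, d, assigned[d.name], config,
            coverage=coverage[d.name],
        )
    merged = merge_topographies(
        offsets_by_det, norm_cov, assigned, sample.t_vox, sample.nz
    )
    return IRResult(
        merged_offsets=merged, offsets_by_det=offsets_by_det,
        coverage=coverage, norm_coverage=norm_cov, assigned=assigned,
        sample=sample, config=config,
        log={"ir_os": config.ir_os, "delta": config.delta, "seed": config.seed},
    )
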