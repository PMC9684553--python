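"""Inverse reconstruction: coverage, seeds, cones, candidate
enumeration, scoring and merging."""

import itertools

import numpy as np
import pytest

from conftest import reference_line_integral
from xrftopo import constants as xc
from xrftopo.forward import BeamConfig, line_key, xrf_maps
from xrftopo.geometry import DetectorSpec, default_detectors
from xrftopo.grid import VoxelGrid
from xrftopo.recon import (
    DerivedSample, IRConfig, conical_roi, coverage_map, enumerate_candidates,
    merge_topographies, reconstruct, reconstruct_detector, select_seed_and_line,
)

LOVO = {"C": 0.61, "N": 0.17, "O": 0.16, "H": 0.06}


def grid_from_columns(t_vox, offsets, nz, vs=1.0, density=1.25, fractions=LOVO):
    fr2d = {s: np.full(t_vox.shape, w) for s, w in fractions.items()}
    return VoxelGrid.from_columns(np.asarray(t_vox), offsets, nz, vs, density, fr2d)


def derived_from_truth(grid, beam, lines=(("C", "K-alpha"),)):
    """Exact per-pixel sample description (no FP bias): the scoring
    forward model fed with the generating grid's own composition."""
    vs = grid.voxel_size
    t_vox = np.round(grid.thickness_map() / vs).astype(np.int64)
    fp = t_vox > 0
    mu0 = grid.mu_rho(beam.E0_eV).max(axis=0)
    mu_line, emf = {}, {}
    for el, ln in lines:
        key = line_key(el, ln)
        mu_line[key] = grid.mu_rho(xc.line_energy(el, ln)).max(axis=0)
        rec = xc.get_element(el)
        w = grid.fractions[el].max(axis=0)
        rho = grid.density.max(axis=0)
        emf[key] = np.where(
            fp,
            w * rho * rec.tau(beam.E0_eV)
            * xc.yield_factor(rec.line(ln), 1.0) * beam.I0 * vs * 1e-4,
            0.0,
        )
    return DerivedSample(voxel_size=vs, nz=grid.shape[0], t_vox=t_vox,
                         mu_rho0=mu0, mu_rho_line=mu_line, em_factor=emf)


def east_detector(extent, **kw):
    return DetectorSpec(name="E", azimuth_deg=90.0,
                        anchor_xy=(extent / 2, extent / 2), **kw)


class TestCoverageMap:
    def test_empty_map_is_zero(self):
        det = east_detector(8.0)
        cov = coverage_map(np.zeros((8, 8)), 1.0, det)
        assert np.all(cov == 0)

    def test_isolated_column_not_self_shielded(self):
        t = np.zeros((8, 8))
        t[4, 4] = 5.0
        cov = coverage_map(t, 1.0, east_detector(8.0))
        assert cov[4, 4] == 0.0

    def test_two_column_shadowing_matches_line_integral_oracle(self):
        t = np.zeros((11, 11))
        t[5, 5] = 1.0   # rear column
        t[5, 8] = 4.0   # shielding column toward the East detector
        det = east_detector(11.0)
        cov = coverage_map(t, 1.0, det)
        g = grid_from_columns(t.astype(np.int64), None, 5)
        occ = g.occupancy.astype(float)
        p0 = np.array([5.5, 5.5, 1.0])  # top center of the rear column
        ref = reference_line_integral(occ, 1.0, p0, det.face_center)
        assert cov[5, 5] == pytest.approx(ref, rel=1e-9)
        assert cov[5, 5] > 0.5  # the front column really intervenes
        assert cov[5, 8] == 0.0


class TestSeedAndLine:
    def test_single_pixel_footprint(self):
        elig = np.zeros((6, 6), dtype=bool)
        elig[3, 2] = True
        line = select_seed_and_line(np.zeros((6, 6)), elig, east_detector(6.0), 1)
        assert line[0] == (3, 2)

    def test_uniform_coverage_row_major_tie_break(self):
        elig = np.ones((4, 4), dtype=bool)
        line = select_seed_and_line(np.ones((4, 4)), elig, east_detector(4.0), 1)
        assert line[0] == (0, 0)

    def test_line_runs_away_from_detector(self):
        elig = np.zeros((6, 6), dtype=bool)
        elig[3, 4] = True
        line = select_seed_and_line(np.zeros((6, 6)), elig, east_detector(6.0), 1)
        xs = [x for _, x in line]
        assert xs == sorted(xs, reverse=True)  # walking West, away from E

    def test_no_eligible_pixels_empty(self):
        out = select_seed_and_line(np.ones((4, 4)), np.zeros((4, 4), bool),
                                   east_detector(4.0), 1)
        assert out == []


class TestConicalRoi:
    def test_vanishing_face_degenerates_to_line(self):
        det = east_detector(9.0, face_side_um=1e-6)
        roi = conical_roi((4, 4), det, (9, 9))
        assert roi[0] == (4, 4)
        assert all(y == 4 for y, _ in roi)
        assert sorted(x for _, x in roi) == list(range(4, 9))

    def test_apex_at_detector_side_edge_is_alone(self):
        det = east_detector(9.0)
        roi = conical_roi((4, 8), det, (9, 9))
        assert roi == [(4, 8)]

    def test_members_match_wedge_oracle(self):
        det = east_detector(21.0)
        apex = (10, 2)
        roi = set(conical_roi(apex, det, (21, 21)))
        half = np.arctan(0.5 * det.face_side_um / det.distance_um)
        for y, x in itertools.product(range(21), range(21)):
            s = x - apex[1]          # toward East
            lat = abs(y - apex[0])
            inside = s >= 0 and lat <= max(s * np.tan(half), 0.5)
            assert ((y, x) in roi) == inside

    def test_ordered_by_distance_from_apex(self):
        det = east_detector(21.0)
        roi = conical_roi((10, 2), det, (21, 21))
        d = [(y - 10) ** 2 + (x - 2) ** 2 for y, x in roi]
        assert d == sorted(d)


class TestEnumerateCandidates:
    def test_single_pixel_count(self):
        out = enumerate_candidates(np.array([3]), np.array([False]),
                                   np.array([0]), nz=10, delta=10**6)
        assert out.shape == (8, 1)  # 10 - 3 + 1
        assert list(out[:, 0]) == list(range(8))

    def test_two_adjacent_pixels_match_brute_force(self):
        t = np.array([2, 2])
        out = enumerate_candidates(t, np.array([False, False]),
                                   np.zeros(2, int), nz=4, delta=10**6)
        brute = [
            (o1, o2)
            for o1 in range(3) for o2 in range(3)
            if o2 <= o1 + 1 and o1 <= o2 + 1  # interval overlap >= 1
        ]
        assert [tuple(r) for r in out] == sorted(brute)

    def test_delta_one_takes_first(self):
        out = enumerate_candidates(np.array([2, 2]), np.array([False, False]),
                                   np.zeros(2, int), nz=4, delta=1)
        assert out.shape == (1, 2)
        assert tuple(out[0]) == (0, 0)

    def test_equidistant_subsampling(self):
        full = enumerate_candidates(np.array([3]), np.array([False]),
                                    np.array([0]), nz=12, delta=10**6)
        sub = enumerate_candidates(np.array([3]), np.array([False]),
                                   np.array([0]), nz=12, delta=5)
        assert len(full) == 10 and len(sub) == 5
        assert [tuple(r) for r in sub] == [tuple(full[i]) for i in (0, 2, 4, 6, 8)]

    def test_unlinked_pairs_unconstrained(self):
        out = enumerate_candidates(np.array([1, 1]), np.array([False, False]),
                                   np.zeros(2, int), nz=3, delta=10**6,
                                   linked=np.array([False]))
        assert len(out) == 9  # 3 x 3, no overlap constraint

    def test_conflicting_frozen_neighbors_infeasible(self):
        t = np.array([1, 1, 1])
        fixed = np.array([True, False, True])
        out = enumerate_candidates(t, fixed, np.array([0, 0, 4]), nz=5, delta=100)
        assert out is None

    def test_frozen_members_pinned(self):
        t = np.array([2, 2])
        out = enumerate_candidates(t, np.array([True, False]),
                                   np.array([2, 0]), nz=5, delta=10**6)
        assert np.all(out[:, 0] == 2)
        assert set(out[:, 1]) == {1, 2, 3}


class TestReconstructDetector:
    def test_flat_slab_self_recovery(self):
        """Support-resting truth is recovered exactly: every lifted
        candidate scores strictly worse than the resting one."""
        t = np.zeros((7, 7), dtype=np.int64)
        t[2:5, 2:5] = 2
        truth = grid_from_columns(t, None, 5)
        beam = BeamConfig()
        det = east_detector(7.0)
        ms = xrf_maps(truth, beam, [det], [("C", "K-alpha")])
        sample = derived_from_truth(truth, beam)
        off = reconstruct_detector(ms.maps["E"], sample, det,
                                   t > 0, IRConfig(ir_os=1.0, delta=10**6))
        assert np.all(off[t > 0] == 0)

    def test_exhaustive_search_equals_independent_global_optimum(self):
        """Single-row toy where one cone covers every column: the IR's
        internal scorer must pick the same placement as a brute-force
        search scored by the full 3D forward simulator."""
        ny = nx = 6
        nz = 5
        t = np.zeros((ny, nx), dtype=np.int64)
        t[3, 1:4] = (2, 3, 2)
        true_off = np.zeros((ny, nx), dtype=np.int64)
        true_off[3, 1:4] = (1, 0, 1)
        truth = grid_from_columns(t, true_off, nz)
        beam = BeamConfig()
        det = east_detector(float(nx))
        ms = xrf_maps(truth, beam, [det], [("C", "K-alpha")])
        sample = derived_from_truth(truth, beam)

        got = reconstruct_detector(ms.maps["E"], sample, det, t > 0,
                                   IRConfig(ir_os=1.0, delta=10**6))

        # independent oracle: enumerate all gap-free placements of the
        # three columns, score each by a fresh forward simulation
        target = ms.maps["E"]["C_K-alpha"]
        cells = [(3, 1), (3, 2), (3, 3)]
        best, best_score = None, np.inf
        for o1 in range(nz - 2 + 1):
            for o2 in range(nz - 3 + 1):
                if not (o1 <= o2 + 2 and o2 <= o1 + 1):
                    continue
                for o3 in range(nz - 2 + 1):
                    if not (o2 <= o3 + 1 and o3 <= o2 + 2):
                        continue
                    off = np.zeros((ny, nx), dtype=np.int64)
                    off[3, 1:4] = (o1, o2, o3)
                    cand = grid_from_columns(t, off, nz)
                    sim = xrf_maps(cand, beam, [det], [("C", "K-alpha")])
                    score = sum(abs(sim.maps["E"]["C_K-alpha"][c] - target[c])
                                for c in cells)
                    if score < best_score - 1e-12:
                        best, best_score = (o1, o2, o3), score
        assert tuple(got[3, 1:4]) == best == tuple(true_off[3, 1:4])

    def test_deterministic(self, truth_grid, beam):
        det = east_detector(40.0)
        ms = xrf_maps(truth_grid, beam, [det], [("C", "K-alpha")])
        sample = derived_from_truth(truth_grid, beam)
        elig = sample.t_vox > 0
        cfg = IRConfig(ir_os=1.0, delta=50)
        a = reconstruct_detector(ms.maps["E"], sample, det, elig, cfg)
        b = reconstruct_detector(ms.maps["E"], sample, det, elig, cfg)
        assert np.array_equal(a, b)


class TestMerge:
    def test_single_detector_identity(self):
        t = np.array([[2, 2]])
        off = np.array([[1, 0]])
        merged = merge_topographies({"E": off}, {"E": np.zeros((1, 2))},
                                    {"E": np.ones((1, 2), bool)}, t, nz=5)
        assert np.array_equal(merged, off)

    def test_equal_weights_average_offsets(self):
        t = np.array([[2]])
        merged = merge_topographies(
            {"E": np.array([[0]]), "W": np.array([[2]])},
            {"E": np.array([[0.5]]), "W": np.array([[0.5]])},
            {"E": np.ones((1, 1), bool), "W": np.ones((1, 1), bool)},
            t, nz=5,
        )
        assert merged[0, 0] == 1

    def test_thickness_preserved_and_inside_grid(self, truth_grid, beam):
        sample = derived_from_truth(truth_grid, beam)
        rng = np.random.default_rng(3)
        offs, ncov, assigned = {}, {}, {}
        for name in ("E", "W", "N"):
            o = rng.integers(0, 3, sample.t_vox.shape)
            offs[name] = np.minimum(o, np.maximum(sample.nz - sample.t_vox, 0))
            ncov[name] = rng.uniform(0, 1, sample.t_vox.shape)
            assigned[name] = rng.uniform(size=sample.t_vox.shape) < 0.7
        merged = merge_topographies(offs, ncov, assigned, sample.t_vox, sample.nz)
        assert np.all(merged >= 0)
        assert np.all(merged + sample.t_vox <= sample.nz)
        # column heights unchanged by construction
        z = np.arange(sample.nz)[:, None, None]
        occ = (z >= merged[None]) & (z < (merged + sample.t_vox)[None])
        assert np.array_equal(occ.sum(axis=0), sample.t_vox)


def test_full_reconstruct_is_deterministic_and_valid(truth_grid, beam):
    dets = default_detectors((40.0, 40.0))
    ms = xrf_maps(truth_grid, beam, dets, [("C", "K-alpha")])
    sample = derived_from_truth(truth_grid, beam)
    cfg = IRConfig(ir_os=0.0, delta=30)
    a = reconstruct(ms, sample, dets, cfg)
    b = reconstruct(ms, sample, dets, cfg)
    assert np.array_equal(a.merged_offsets, b.merged_offsets)
    occ = a.occupancy()
    assert np.array_equal(occ.sum(axis=0), sample.t_vox)  # thickness kept
    grid = a.to_grid(1.25, {s: np.full(sample.t_vox.shape, w) for s, w in LOVO.items()})
    grid.validate()  # gap-free columns
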