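"""Forward simulator: Beer-Lambert profiles, emission, exit-path
tracing, the K matrix and the map-level products."""

import numpy as np
import pytest

from conftest import make_slab, reference_line_integral
from xrftopo import constants as xc
from xrftopo.forward import (
    BeamConfig, emission_matrix, incident_profile, self_absorption_K,
    stxm_map, trace_path_transmission, xrf_maps,
)
from xrftopo.fp import k_fp
from xrftopo.geometry import DetectorSpec, default_detectors
from xrftopo.grid import VoxelGrid
from xrftopo.phantom import PhantomSpec, build_phantom, canonical_spec
from xrftopo.tracing import line_integral_3d

LOVO = {"C": 0.61, "N": 0.17, "O": 0.16, "H": 0.06}


class TestIncidentProfile:
    def test_empty_grid_everywhere_i0(self):
        g = VoxelGrid.empty((4, 3, 3), elements=("C",))
        beam = BeamConfig()
        assert np.allclose(incident_profile(g, beam), beam.I0)

    def test_homogeneous_column_analytic(self):
        g = make_slab(t_vox=4, nz=4)
        beam = BeamConfig()
        mu_rho = g.mu_rho(beam.E0_eV)[0, 2, 2]
        prof = incident_profile(g, beam)[:, 2, 2]
        # beam enters at the top (z = nz); voxel centers at depth
        # (nz - k - 0.5) voxels below the surface
        for k in range(4):
            depth = (4 - k - 0.5) * g.voxel_size
            assert prof[k] == pytest.approx(beam.I0 * np.exp(-mu_rho * depth))

    def test_two_layer_column_is_product_of_transmissions(self):
        g = VoxelGrid.empty((2, 1, 1), elements=("C", "O"))
        g.occupancy[:] = True
        g.density[:] = [[[2.0]], [[0.5]]]
        g.fractions["C"][1] = 1.0
        g.fractions["O"][0] = 1.0
        beam = BeamConfig()
        mu_c = float(xc.get_element("C").mu(beam.E0_eV)) * 1e-4
        mu_o = float(xc.get_element("O").mu(beam.E0_eV)) * 1e-4
        prof = incident_profile(g, beam)
        # bottom voxel: full top layer (C, rho=0.5) + half its own (O, rho=2)
        assert prof[0, 0, 0] == pytest.approx(
            beam.I0 * np.exp(-mu_c * 0.5) * np.exp(-mu_o * 2.0 * 0.5)
        )


class TestEmissionMatrix:
    def test_surface_voxel_analytic(self):
        g = make_slab(t_vox=1, nz=1, density=1.25)
        beam = BeamConfig()
        em = emission_matrix(g, beam, "C", solid_angle_fraction=0.01)
        el = xc.get_element("C")
        ln = el.line("K-alpha")
        mu_rho = g.mu_rho(beam.E0_eV)[0, 0, 0]
        expect = (
            0.61 * 1.25 * float(el.tau(beam.E0_eV))
            * xc.yield_factor(ln, 0.01) * beam.I0
            * np.exp(-0.5 * mu_rho) * 1e-4
        )
        assert em[0, 2, 2] == pytest.approx(expect, rel=1e-12)

    def test_absent_element_gives_zero_matrix(self):
        g = make_slab()
        assert np.all(emission_matrix(g, BeamConfig(), "Mg") == 0)

    def test_line_above_beam_energy_warns_and_zeroes(self):
        g = make_slab()
        with pytest.warns(UserWarning, match="below the Mg K edge"):
            em = emission_matrix(g, BeamConfig(E0_eV=1000.0), "Mg")
        assert np.all(em == 0)


class TestTracePathTransmission:
    def test_vacuum_path_is_one(self):
        g = VoxelGrid.empty((4, 4, 4), elements=("C",))
        assert trace_path_transmission((2.0, 2.0, 0.5), (2.0, 2.0, 40.0), g, 277.0) == 1.0

    def test_unit_optical_depth(self):
        # straight vertical exit, mu.rho * path == 1 -> e^-1
        g = make_slab(t_vox=4, nz=4, density=1.25)
        mu_rho = g.mu_rho(277.0)[0, 2, 2]
        path = 1.0 / mu_rho
        p0 = (2.5, 2.5, 4.0 - path)
        assert trace_path_transmission(p0, (2.5, 2.5, 50.0), g, 277.0) == pytest.approx(
            np.exp(-1.0), rel=1e-9
        )

    def test_degenerate_zero_length_path(self):
        g = make_slab()
        assert trace_path_transmission((1.0, 1.0, 1.0), (1.0, 1.0, 1.0), g, 277.0) == 1.0

    def test_oblique_path_matches_plane_crossing_oracle(self):
        rng = np.random.default_rng(7)
        g = VoxelGrid.empty((3, 3, 3), elements=("C",))
        g.occupancy[:] = True
        g.density[:] = rng.uniform(0.5, 2.0, (3, 3, 3))
        g.fractions["C"][:] = 1.0
        field = g.mu_rho(277.0)
        for _ in range(10):
            p0 = rng.uniform(0.2, 2.8, 3)
            p1 = rng.uniform(-5.0, 8.0, 3)
            p1[2] = 9.0  # exit through the top, well outside
            got = line_integral_3d(field, 1.0, p0, p1)
            ref = reference_line_integral(field, 1.0, p0, p1)
            assert got == pytest.approx(ref, rel=1e-9, abs=1e-12)


class TestSelfAbsorptionK:
    def test_empty_grid_k_is_one(self, detectors):
        g = VoxelGrid.empty((4, 5, 5), elements=("C",))
        k = self_absorption_K(g, detectors[0], 277.0)
        assert np.all(k == 1.0)

    def test_k_in_unit_interval(self, detectors):
        g = make_slab(t_vox=3, nz=4)
        k = self_absorption_K(g, detectors[0], 277.0)
        assert np.all(k > 0.0) and np.all(k <= 1.0)

    def test_doubling_density_never_increases_k(self, detectors):
        g1 = make_slab(t_vox=3, nz=4, density=1.0)
        g2 = make_slab(t_vox=3, nz=4, density=2.0)
        k1 = self_absorption_K(g1, detectors[0], 277.0)
        k2 = self_absorption_K(g2, detectors[0], 277.0)
        assert np.all(k2 <= k1 + 1e-12)

    @pytest.mark.parametrize("h_um", [1.0, 5.0, 10.0])
    def test_uniform_slab_matches_closed_form_kfp(self, h_um):
        """Pixel-summed K-weighted emission over the unattenuated column
        emission equals the closed-form uniform-column factor within 2%
        (wide slab so no exit ray leaves through the sides; small face
        so the take-off spread is negligible)."""
        vs, n = 0.5, 81
        beam = BeamConfig()
        det = DetectorSpec(name="E", azimuth_deg=90.0, face_side_um=500.0,
                           n_face_points=9, anchor_xy=(n * vs / 2, n * vs / 2))
        tv = int(round(h_um / vs))
        g = make_slab(ny=n, nx=n, t_vox=tv, nz=tv + 1, voxel_size=vs, density=1.25)
        em = emission_matrix(g, beam, "C", solid_angle_fraction=det.solid_angle_fraction)
        c = n // 2
        targets = det.face_targets()
        num = 0.0
        for k in range(tv):
            p0 = ((c + 0.5) * vs, (c + 0.5) * vs, (k + 0.5) * vs)
            kk = np.mean([trace_path_transmission(p0, t, g, 277.0) for t in targets])
            num += em[k, c, c] * kk
        el = xc.get_element("C")
        unatt = (0.61 * 1.25 * float(el.tau(beam.E0_eV))
                 * xc.yield_factor(el.line("K-alpha"), det.solid_angle_fraction)
                 * beam.I0 * h_um * 1e-4)
        kfp = k_fp(h_um, 1.25, xc.mixture_mu(LOVO, beam.E0_eV),
                   xc.mixture_mu(LOVO, 277.0), 1.0,
                   det.mean_cosec_phi(((c + 0.5) * vs, (c + 0.5) * vs)))
        assert num / unatt == pytest.approx(kfp, rel=0.02)


class TestXrfMaps:
    def test_map_equals_z_sum_of_em_times_k(self, detectors):
        g = make_slab(t_vox=2, nz=3)
        beam = BeamConfig()
        det = detectors[0]
        ms = xrf_maps(g, beam, [det], [("C", "K-alpha")])
        em = emission_matrix(g, beam, "C", solid_angle_fraction=det.solid_angle_fraction)
        k = self_absorption_K(g, det, 277.0)
        assert np.allclose(ms.maps[det.name]["C_K-alpha"], (em * k).sum(axis=0))

    def test_thin_vacuum_like_sample_k_is_one(self, detectors):
        g = make_slab(t_vox=1, nz=2, density=1e-9)
        beam = BeamConfig()
        ms = xrf_maps(g, beam, detectors[:1], [("C", "K-alpha")])
        em = emission_matrix(g, beam, "C",
                             solid_angle_fraction=detectors[0].solid_angle_fraction)
        assert np.allclose(ms.maps[detectors[0].name]["C_K-alpha"],
                           em.sum(axis=0), rtol=1e-6)

    def test_mirror_symmetry_of_opposed_detectors(self):
        # single central hemisphere: E and W detector maps are x-mirrors
        spec = PhantomSpec(grid_shape=(20, 20, 10), hemispheres=((10.0, 10.0, 6.0),))
        g = build_phantom(spec)
        dets = default_detectors((20.0, 20.0))
        by = {d.name: d for d in dets}
        ms = xrf_maps(g, BeamConfig(), [by["E"], by["W"]], [("C", "K-alpha")])
        east = ms.maps["E"]["C_K-alpha"]
        west = ms.maps["W"]["C_K-alpha"]
        assert np.allclose(east, west[:, ::-1], atol=1e-9 * east.max())

    def test_directional_shadowing(self, truth_grid, detectors):
        """Pixels strongly shielded toward one detector report fewer
        counts there than toward the opposite, unshielded detector."""
        from xrftopo.recon import coverage_map

        by = {d.name: d for d in detectors}
        ms = xrf_maps(truth_grid, BeamConfig(), [by["S"], by["N"]], [("C", "K-alpha")])
        t = truth_grid.thickness_map()
        cov_s = coverage_map(t, 1.0, by["S"])
        cov_n = coverage_map(t, 1.0, by["N"])
        shadowed = (cov_s - cov_n) > 5.0
        assert shadowed.sum() > 10
        assert (ms.maps["S"]["C_K-alpha"][shadowed].sum()
                < ms.maps["N"]["C_K-alpha"][shadowed].sum())

    def test_bit_identical_determinism_with_noise_seed(self, detectors):
        g = make_slab()
        a = xrf_maps(g, BeamConfig(I0=1e4), detectors[:2], [("C", "K-alpha")],
                     poisson_seed=11)
        b = xrf_maps(g, BeamConfig(I0=1e4), detectors[:2], [("C", "K-alpha")],
                     poisson_seed=11)
        for d in a.maps:
            for key in a.maps[d]:
                assert np.array_equal(a.maps[d][key], b.maps[d][key])
        assert np.array_equal(a.stxm, b.stxm)

    def test_stxm_is_full_column_transmission(self):
        g = make_slab(t_vox=4, nz=4)
        beam = BeamConfig()
        mu_rho = g.mu_rho(beam.E0_eV)[0, 2, 2]
        assert stxm_map(g, beam)[2, 2] == pytest.approx(np.exp(-mu_rho * 4.0))


def test_beam_validation():
    with pytest.raises(ValueError):
        BeamConfig(I0=0)
    with pytest.raises(ValueError):
        BeamConfig(E0_eV=50.0)
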