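"""End-to-end orchestration: phantom -> forward maps -> z-map ->
first-pass quantification -> inverse reconstruction -> correction
metrics.  This is the programmatic equivalent of the CLI ``pipeline``
subcommand and the entry point used by the examples and the
acceptance measurements."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluate import evaluate_correction, jaccard_index, volume_overlap
from .forward import BeamConfig, XRFMapSet, xrf_maps
from .fp import quantify
from .geometry import default_detectors
from .grid import VoxelGrid
from .phantom import LOVO_DENSITY, canonical_spec, build_phantom
from .recon import DerivedSample, IRConfig, IRResult, reconstruct
from .zmap import ZMapState, derive_zmap

__all__ = ["PipelineResult", "run_pipeline", "zmap_errors"]

ALL_LINES = (("C", "K-alpha"), ("N", "K-alpha"), ("O", "K-alpha"), ("Mg", "K-alpha"))


@dataclass
class PipelineResult:
    truth: VoxelGrid
    mapset: XRFMapSet
    zstate: ZMapState
    fractions: dict
    ir: IRResult
    overlap_pct: float
    jaccard: float
    volume_diff_pct: float
    detectors: list
    beam: BeamConfig
    extras: dict = field(default_factory=dict)


def zmap_errors(zstate: ZMapState, truth: VoxelGrid, beam: BeamConfig):
    """Mean +/- sd percentage difference of the recovered thickness and
    mu_s(E0) rho maps against the truth, over footprint pixels."""
    t_true = truth.thickness_map()
    mask = (t_true > 0) & zstate.footprint
    mu_rho_true = truth.mu_rho(beam.E0_eV).max(axis=0)  # column-constant
    dz = 100.0 * (zstate.z[mask] - t_true[mask]) / t_true[mask]
    dm = 100.0 * (zstate.mu_rho[mask] - mu_rho_true[mask]) / mu_rho_true[mask]
    return (
        (float(dz.mean()), float(dz.std())),
        (float(dm.mean()), float(dm.std())),
    )


def run_pipeline(
    upscale: float = 1.0,
    voxel_size: float = 1.0,
    ir_os: float = 0.2,
    delta: int = 1000,
    I0: float = 1e8,
    E0_eV: float = 1500.0,
    n_iter: int = 1000,
    poisson_seed: int | None = None,
    n_face_points: int = 9,
    stride: int | None = None,
    with_metrics: bool = False,
) -> PipelineResult:
    """Run the canonical study end to end and measure the topography
    recovery.  ``poisson_seed`` switches shot noise on for the target
    maps (used for low-I0 robustness runs)."""
    spec = canonical_spec(upscale=upscale, voxel_size=voxel_size)
    truth = build_phantom(spec)
    nz, ny, nx = truth.shape
    beam = BeamConfig(E0_eV=E0_eV, I0=I0)
    detectors = default_detectors(
        extent_xy_um=(nx * voxel_size, ny * voxel_size),
        n_face_points=n_face_points,
    )
    mapset = xrf_maps(truth, beam, detectors, list(ALL_LINES), poisson_seed=poisson_seed)

    h_max = float(truth.thickness_map().max())
    zstate = derive_zmap(mapset.stxm, rho_avg=LOVO_DENSITY, h_max=h_max, n_iter=n_iter)

    elements = [e for e, _ in ALL_LINES]
    fractions = quantify(mapset, detectors, beam, elements,
                         pixel_area_um2=voxel_size**2)
    derived = DerivedSample.from_first_pass(
        zstate, fractions, beam, voxel_size, nz, lines=(("C", "K-alpha"),)
    )
    config = IRConfig(ir_os=ir_os, delta=delta, stride=stride,
                      n_face_points=n_face_points,
                      seed=poisson_seed if poisson_seed is not None else 0)
    ir = reconstruct(mapset, derived, detectors, config)

    occ = ir.occupancy()
    overlap = volume_overlap(occ, truth.occupancy)
    jac = jaccard_index(occ, truth.occupancy)
    v_truth = truth.volume()
    v_rec = float(occ.sum()) * voxel_size**3
    res = PipelineResult(
        truth=truth, mapset=mapset, zstate=zstate, fractions=fractions,
        ir=ir, overlap_pct=overlap, jaccard=jac,
        volume_diff_pct=100.0 * (v_rec - v_truth) / v_truth,
        detectors=detectors, beam=beam,
    )
    if with_metrics:
        res.extras["metrics"] = correction_metrics(res)
    return res


def correction_metrics(res: PipelineResult):
    """Build the corrected / uncorrected grids on the reconstructed
    topography and evaluate the correction against the truth."""
    truth = res.truth
    sample = res.ir.sample
    # correct fractions: the truth's own per-pixel composition pattern
    fr_true_2d = {
        s: np.where(truth.footprint(), w.max(axis=0), 0.0)
        for s, w in truth.fractions.items()
    }
    recon_correct = res.ir.to_grid(LOVO_DENSITY, fr_true_2d)
    # uncorrected fractions: biased first-pass maps; density from mu rho
    fr_hat = {s: np.nan_to_num(w) for s, w in res.fractions.items()}
    from .fp import mu_maps  # local import to avoid cycle at module load

    mu0 = mu_maps(res.fractions, [res.beam.E0_eV])[res.beam.E0_eV]
    rho_hat = np.where(np.nan_to_num(mu0) > 0,
                       sample.mu_rho0 * 1e4 / np.where(np.nan_to_num(mu0) > 0,
                                                       np.nan_to_num(mu0), 1.0),
                       0.0)
    recon_uncorrected = res.ir.to_grid(np.maximum(rho_hat, 1e-12), fr_hat)
    return evaluate_correction(
        recon_correct, recon_uncorrected, truth, res.beam, res.detectors,
        mask=truth.footprint(),
    )
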