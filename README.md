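# xrftopo

Self-absorption modelling and 3D topography reconstruction for
low-energy X-ray fluorescence (XRF) microscopy.

Soft-XRF maps of light elements (C, N, O) in cells and tissue are
distorted by the sample itself: a photon emitted deep inside a cell
must cross microns of organic matter to reach a silicon drift detector
(SDD), and at 277 eV (C Kα) the attenuation length is ~1 μm. Because
every detector in a multi-detector system sees the sample through a
different exit path, the distortion encodes the sample's 3D shape.
`xrftopo` exploits that: from the 2D count maps of eight compass-
arranged SDDs, one STXM transmission map, an average density and a
maximum expected thickness, it reconstructs a voxelized 3D topography
by ray-traced forward simulation and combinatorial search, then uses
the recovered shape to undo the self-absorption quantitatively.

The package implements, for sample voxels with mass fractions `w_j`
and density `ρ`:

* emission per voxel
  `EM_ij = w_j ρ τ_j(E0) (Ω/4π) ω_j p_ij J_j I0 e^{−μ_s(E0)ρz} dz`,
  self-absorption `K = ⟨e^{−∫μ_s(E_i)ρ dl}⟩` averaged over exit rays
  to each detector face, and measured maps `XRF_2D = Σ_z EM·K`;
* Beer–Lambert thickness retrieval from STXM with iterative
  re-factorization of `μρ·z`;
* fundamental-parameter quantification
  `m_j = C_i S/(I0 Y_ij τ_j K_FP)` with the closed-form
  `K_FP = (1−e^{−x})/x`;
* the per-detector conical-region topography search (coverage maps,
  seed lines, gap-free column permutations capped by the threshold δ,
  L1 scoring against measured maps, oversampling gate `IR_os`) and the
  coverage-weighted merge;
* the correction-quality metrics (least-squares map differences,
  paired t / KS statistics, volume overlap).

## Worked example

```python
from xrftopo.pipeline import run_pipeline

res = run_pipeline(ir_os=0.2, delta=1000)
print(f"volume overlap with truth: {res.overlap_pct:.1f} %")
print(f"total volume difference:   {res.volume_diff_pct:+.1f} %")
```

This builds the bundled three-cell sample (hemispheres of 6, 9 and
12 μm with a colon-carcinoma-like 61/17/16% C/N/O composition at
1.25 g/cm³, plus Mg hot spots), simulates the STXM and all
eight-detector K-α maps at `E0 = 1500 eV`, `I0 = 10⁸` photons/pixel,
retrieves the thickness map, quantifies the (deliberately biased)
first-pass fractions, and reconstructs the 3D sample. It prints:

```
volume overlap with truth: 85.8 %
total volume difference:   -4.5 %
```

i.e. the recovered 3D body shares 85.8% of the true sample's voxels
and misses 4.5% of its volume — the residual comes from the thickness
map, since the reconstruction preserves per-pixel thickness exactly.
The scripts in `examples/` walk the individual stages (forward
simulation, STXM inversion, reconstruction + correction) with printed,
annotated output; `xrftopo --help` exposes the same stages as a
command-line pipeline.

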