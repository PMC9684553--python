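# Methods

`xrftopo` models the self-absorption of soft-X-ray fluorescence (XRF)
in microscopic samples and inverts it: from per-detector 2D XRF count
maps, one STXM transmission map, an average density and a maximum
expected thickness, it reconstructs a voxelized 3D topography and uses
it to correct elemental count maps. This note records the model, the
parameter choices, the numerical decisions, and what the synthetic
studies do and do not demonstrate.

## Forward model

A pencil beam of energy `E0` and integrated intensity `I0` photons per
pixel enters the sample along −z at perpendicular incidence. For a
voxel of element fractions `w_j`, density `ρ` and edge `dz`:

* incident attenuation follows Beer–Lambert through the overburden,
  with the mixture rule `μ_s(E) = Σ_j w_j μ_j(E)`;
* the line-`i` production of element `j` per voxel is
  `EM_ij = w_j ρ τ_j(E0) · (Ω/4π) ω_j p_ij J_j · I0 e^{−μ_s(E0)ρz} dz`,
  with `τ_j` the photoionization cross-section, `ω_j` the fluorescence
  yield, `p_ij` the transition probability and `J_j` the jump factor
  `(r−1)/r` (the K-shell share of photoionization);
* each emitted photon reaches a detector face point with probability
  `exp(−∫ μ_s(E_i) ρ dl)` along the exit ray; the average over the
  face ray targets is the per-voxel self-absorption factor `K ∈ (0,1]`;
* the recorded 2D map is `XRF_2D = Σ_z EM · K`, and the STXM map is
  the full-column transmission at `E0`.

Emission originates at the voxel center: the incident overburden
includes half the voxel's own layer and exit rays start at the center.
This midpoint discretization converges to the closed-form
uniform-column absorption factor
`K_FP = (1−e^{−x})/x`, `x = ρh(μ_s(E0)cosecθ + μ_s(E_i)⟨cosecφ⟩)`
as `O(dz²)`; the test suite verifies agreement within 2% on wide slabs
of 1, 5 and 10 μm. Two caveats the tests make explicit: the closed
form puts the *mean* exit cosecant inside one exponent while the K
matrix averages exponentials over the face (a Jensen gap that grows
with the face's angular size), and a slab must be laterally wider than
`h·cot(elevation)` or exit rays leave through its sides. Secondary
fluorescence, detector response, escape peaks and spectral binning are
not modelled.

No noise is added by default. With a seed, counts are Poisson-resampled
and the STXM is resampled as `Poisson(I0·T)/I0` clipped into (0, 1] —
the transmission detector sees the same exposure as the fluorescence
detectors, so a low-dose study degrades both.

## Physical constants

All constants are served from one frozen JSON table
(`src/xrftopo/data/constants.json`; regenerated by
`scripts/make_constants_tables.py`). Photoionization cross-sections
come from Cromer–Liberman imaginary scattering factors
(`σ = 2 r_e λ f''` per atom, via gemmi), tabulated over 100–3000 eV on
a log grid with points bracketing each K edge so the discontinuity is
preserved under log-log interpolation; total attenuation adds a
forward-Thomson scattering bound (`σ_T Z² N_A/A`, < 2% at these
energies). Hydrogen, below the Cromer–Liberman Z range, carries an
XCOM-anchored power law (`τ_H ≈ 7.2·(1000 eV/E)^3.1 cm²/g`) — it is a
non-fluorescing balance element contributing ~0.1% of the mixture
attenuation at 1.5 keV. K fluorescence yields are the Krause values
(C 0.0028, N 0.0052, O 0.0083, Mg 0.0297); Kα transition
probabilities 1 for C/N/O (no Kβ below Ne) and 0.989 for Mg; jump
ratios are measured from the table's own edge discontinuity
(C 22.3 → jump factor 0.955), keeping every factor self-consistent
with the tabulated `τ(E)`. Because the same table drives both the
forward simulation and the quantification, the package's headline
statistics are invariant to the absolute scale of these constants;
they matter only for realism of the optical depths.

## Instrument geometry

Eight square silicon drift detectors at compass azimuths
(N, NE, …, NW), elevation 30° above the support plane, face centers
28 mm from the grid center, 5 mm face side, aimed at the sample. In
the far field the solid-angle fraction is constant per detector,
`Ω/4π = A/(4πd²) ≈ 2.5×10⁻³`. Exit rays target a deterministic 3×3
grid on each face (`N_α = 9`). The beam energy defaults to 1500 eV —
above the Mg K edge (1305 eV) so all four tracked lines
(C 277, N 392.4, O 524.9, Mg 1253.6 eV) are excited, and a standard
working point for low-energy XRF microprobes. All geometry is
overridable; absolute count rates scale with it, the package's
relative statistics do not.

## Synthetic sample

Three hemispherical cells (radii 6, 9, 12 μm) rest flat on the support
plane of a 40×40×14 μm³ grid at 1 μm voxels, composition 61% C,
17% N, 16% O by mass with a 6% hydrogen balance, density 1.25 g/cm³.
Centers are frozen at calibrated positions where the union footprint
is exactly 778 pixels, with the largest cell facing the other two.
Three 2-μm Mg hot-spot disks (4% Mg, other fractions rescaled) sit
0.6 r off each cell's apex, radially outward from the three-cell
centroid: a hot spot on the single most absorbing pixel would
contaminate the thickness-retrieval scale anchor (below) and is also
the physically unusual case. A 2.5×-scaled variant lives in a
100×100×100 μm³ cube.

What the phantom emulates: cell-scale topography, realistic soft-X-ray
optical depths (the STXM floor is ≈0.27; C-Kα exit depths reach e⁻⁹),
composition heterogeneity along x/y. What it does not: composition
variation along z (assumed homogeneous per column), sub-voxel surface
texture, detector noise other than shot noise, and any real-beamline
background. Passing tests therefore demonstrate the geometry engine
and the inversion logic under the stated model, not performance on
beamline data.

## Thickness retrieval (z-map)

`T = e^{−μρz}` from one energy cannot separate `μρ` from `z`. The
retrieval assigns the maximum expected thickness `h_max` to the most
absorbing pixel(s) (ties within 1e-9 share it) and a globally constant
`μρ = −ln(T_min)/h_max`, inverts all other pixels, then iterates:
pixels whose maximum absolute thickness difference to their
8-neighborhood (sample pixels only) exceeds a threshold are replaced
by the neighbor mean and their `μρ` is recomputed from the STXM, so
`μρ·z` reproduces the measurement exactly at every iteration. The
threshold — the sample-average rate of change — is computed once from
the initial map and then held fixed: a per-iteration mean can never be
satisfied (some pixels always exceed the mean of a non-constant
distribution) and keeps eroding real relief; with the frozen threshold
the update is contractive, converges in a few dozen iterations, and
further iterations are no-ops. Pixels with `T > 0.999` are background.
On the canonical phantom the signed (recovered−true)/true errors are
+2.9% (thickness) and +2.0% (`μρ`) with the Mg pixels and hemisphere
rims carrying most of the scatter. We report signed recovered-vs-true
differences throughout; printed values of this statistic elsewhere are
sign-ambiguous ("difference between the true map and the recovered
one"), so comparisons are made on magnitudes.

## First-pass quantification

Per pixel, `m_j = C_i S/(I0 Y_ij τ_j(E0) K_FP)` with counts pooled
across all eight detectors and the solid angles summed inside `Y_ij`;
`w_j = m_j/Σm`. The first pass *discards* `K_FP` — without a thickness
the correction is unknown — which biases the fractions: on the
canonical phantom the carbon fraction deviates from truth by ≈46% on
average (C Kα at 277 eV sits below the C edge and is the *least*
absorbed of the three light-element lines in this matrix, N Kα the
most). The topography search is designed to be robust to this bias: a
wrong fraction set rescales a detector's simulated map roughly
uniformly, while topography changes reorder pixel intensities.

## Inverse reconstruction

Per detector: a coverage map (occupied path length from each pixel's
column top to the face center; the pixel's own column exempt) ranks
pixels by shielding. The least-shielded unresolved pixel seeds a line
away from the detector; at apexes every `stride` pixels (default: the
cone footprint width at mid-range) a conical region of interest opens
toward the detector — half-angle `atan(face/2d) ≈ 5°`, floored at one
pixel of lateral half-width, clipped at the grid edge. Candidate
topographies rigidly translate the unresolved member columns along z
(range `[0, nz−t]`), previously fixed members frozen, with the
no-vertical-gap rule enforced between consecutive members of the
distance ordering *when they are spatially adjacent* (Chebyshev
distance 1; linking non-neighbours on opposite cone flanks makes
regions spuriously infeasible). Candidates are counted by exact
big-integer dynamic programming over the chain and, when more than `δ`
exist, sampled equidistantly in lexicographic rank (δ = 1 keeps the
first, i.e. all columns support-resting). Each candidate is scored by
the L1 distance between simulated and measured C-Kα counts at the
member pixels; the argmin (first on ties) is fixed in 3D.

Scoring uses a column-interval ray tracer that is exact for rigid
columns, with two documented accelerations: rays precomputed with all
member columns at offset zero are shifted vertically with their source
column (parallel-shift; the neglected parallax is below 0.1% at 28 mm
detector distance), and the optical depth through non-member context
columns is tabulated once per ray per source offset, leaving only the
few member-cell crossings per candidate. On ≤6-cell toys the search
reproduces the global optimum found by brute-force enumeration scored
with the full 3D simulator.

Gating and merging: per pixel, coverages are normalized by the
most-shielded detector; a detector reconstructs the pixel iff its
normalized coverage ≤ `IR_os` (the least-shielded always does, so
`IR_os = 0` means closest-detector-only). Merged column offsets are
the weighted mean over contributing detectors with weights
`1 − normalized coverage` (the stated "coverage values as weights"
must favour the *least* attenuated detectors; the complement is the
reading that does), rounded to the nearest voxel; per-pixel thickness
from the z-map is preserved exactly, so the output has gap-free
columns by construction.

## Correction evaluation

Emission matrices and detector-summed XRF maps are computed on the
reconstructed grid with correct fractions (corrected), on the
reconstructed grid with the biased first-pass fractions (uncorrected)
and on the true grid (reference); the per-pixel squared differences
over the 778 footprint pixels give the mean ± sd statistics, compared
by a paired t-test with a one-sample KS normality check
(significance p < 0.001). Volume overlap is
`100·|recon ∩ truth|/|truth|` — chosen over Jaccard because a
thickness-preserving reconstruction can reach 100%; Jaccard is
reported alongside.

## Problem sizes and measured behaviour

The canonical study (40×40×14 at 1 μm, 8 detectors, `N_α = 9`,
`δ = 1000`) runs in ~1.5 min per reconstruction on one CPU: volume
overlap 85.8% at `IR_os = 0.2`, 87.4% at `IR_os = 1`, recovered volume
−4.5% from truth. The upscaled study keeps the 100×100×100 μm³ cube
and `δ = 10⁴` at 2.5 μm voxels (40³ grid), the package's desk scale
for this variant (~10 min): overlap 79.3%. Coarser voxels quantize
column heights at ±1.25 μm and deepen per-voxel optical depths, both
of which genuinely lower the overlap metric relative to a 1-μm grid.
The low-dose study (I0 = 10³, shot noise on all maps) yields 89.4%:
with ≲10⁻³ expected counts per pixel the XRF targets are almost all
zero, candidates tie, and the deterministic lexicographic tie-break
returns support-resting columns — close to the flat-bottomed truth by
construction. Under this tie-break the low-dose figure is an upper
bound on noise robustness; implementations that break ties differently
can degrade much further.

## Known limitations

* Composition is assumed homogeneous along z everywhere (phantom,
  quantification, reconstruction); layered samples violate this.
* The reconstruction recovers topography only; fractions come from
  the FP passes and no fitting system searches over fraction sets.
* Absolute count rates depend on the (configurable) detector geometry;
  only relative statistics are portable.
* The z-map scale anchor trusts `h_max` and the most absorbing pixel;
  a contaminant hot spot on that pixel biases every thickness.
* Cromer–Liberman factors lose accuracy below ~200 eV; the C-Kα
  (277 eV) regime is near the edge of their comfort zone, adequate
  here because all statistics are self-consistent in the constants.
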