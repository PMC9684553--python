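"""Recover the sample thickness map from a single STXM scan.

Beer-Lambert inversion of one transmission map cannot separate
thickness from density; the iterative retrieval anchors the scale at
the most absorbing pixel (given a maximum expected thickness) and then
re-factorizes pixels whose thickness jumps against their neighbors.
"""

import numpy as np

from xrftopo import BeamConfig, build_phantom, canonical_spec, derive_zmap
from xrftopo.forward import stxm_map

truth = build_phantom(canonical_spec())
beam = BeamConfig()
stxm = stxm_map(truth, beam)

state = derive_zmap(stxm, rho_avg=1.25, h_max=12.0, n_iter=1000)

t_true = truth.thickness_map()
m = state.footprint & (t_true > 0)
dz = 100.0 * (state.z[m] - t_true[m]) / t_true[m]
mu_true = truth.mu_rho(beam.E0_eV).max(axis=0)
dm = 100.0 * (state.mu_rho[m] - mu_true[m]) / mu_true[m]

print(f"converged after {state.iterations_run} iterations "
      f"(threshold {state.threshold_history[0]:.2f} um/px)")
print(f"thickness error:  {dz.mean():+.1f} +/- {dz.std():.1f} % per pixel")
print(f"mu.rho error:     {dm.mean():+.1f} +/- {dm.std():.1f} % per pixel")
print("A few percent mean error: the anchor pixel fixes the absolute scale,")
print("the smoothing mostly reshapes the steep hemisphere rims and the Mg")
print("hot spots where the constant-mu.rho assumption is locally wrong.")
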