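"""Reconstruct the 3D topography from 2D maps and correct the counts.

The full chain: forward maps -> z-map -> first-pass FP fractions
(K_FP omitted, hence biased) -> per-detector ray-tracing topography
search -> merge -> volume overlap against the known truth, then the
self-absorption correction quality on the recovered 3D structure.

Takes a few minutes on one CPU.
"""

from xrftopo.pipeline import correction_metrics, run_pipeline

res = run_pipeline(ir_os=0.2, delta=1000)

print(f"volume overlap with truth: {res.overlap_pct:.1f} %")
print(f"total volume difference:   {res.volume_diff_pct:+.1f} %")
print(f"Jaccard index:             {res.jaccard:.3f}")

rep = correction_metrics(res)
print("\nmean least-squares difference from the simulated truth")
print("(detector-summed XRF maps, corrected vs uncorrected fractions):")
for el, d in rep.per_element.items():
    print(f"  {el}: corrected {d['d_sxrf_c'][0]:9.3g}   "
          f"uncorrected {d['d_sxrf_u'][0]:9.3g}   "
          f"paired-t p = {d['sxrf_stats']['t_p']:.2g}")
print("Corrected maps sit closer to the truth for every element: knowing")
print("the 3D shape lets the per-voxel absorption factors be computed and")
print("the lost counts restored.")
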