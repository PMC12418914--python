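"""Dynamic glucose-uptake experiment on a small phantom, end to end.

Runs the full chain (simulate -> recon -> WSVD -> tMPPCA -> fit ->
quantify) over a baseline frame plus five ~8.5 min frames, then prints the
kidney glucose time course, the exclusion bookkeeping, and the QC table.
"""

import numpy as np

from dmipipe import (
    AcquisitionParams,
    Compartment,
    PhantomSpec,
    RelaxationAssumptions,
    run_pipeline,
    uptake_curve,
)
from dmipipe.pipeline import frame_times

acq = AcquisitionParams(matrix=(10, 10, 8), fov=(120.0, 120.0, 96.0), n_rings=8)
relax = RelaxationAssumptions()
hdo = relax.natural_hdo_mM

uptake = ("gamma_variate", {"C0": 0.0, "A": 2.0, "t_p": 37.0, "alpha": 2.0})
spec = PhantomSpec(
    matrix=acq.matrix,
    fov=acq.fov,
    compartments=[
        Compartment("abdomen", (0, 0, 0), (55, 45, 45), {"water": hdo},
                    linewidth_hz=15.0),
        Compartment("kidney_left", (18, 6, 0), (22, 22, 30), {"water": hdo},
                    linewidth_hz=14.0, uptake={"glc": uptake}),
    ],
    noise_sd=15.0,
    seed=0,
)

times = np.concatenate([[0.0], frame_times(5) + 8.5])
result = run_pipeline(spec, acq, relax, times_min=times, denoise_patch=(4, 4, 4))

tc = result.timecourse("glc")
truth = uptake_curve(*uptake, times)
print("t [min]   glc est [mM]   glc true [mM]")
for t, est, tr in zip(times, tc.values, truth):
    print(f"{t:7.1f}   {est:12.2f}   {tr:13.2f}")

last = result.exclusion_counts[-1]
print(f"\nlast frame: {last['n_excluded']} of {last['n_mask']} kidney voxels "
      f"excluded ({last['percent_excluded']:.1f}%)")
print("\nQC per frame:")
print(result.qc_table().round(2).to_string(index=False))
# The estimates track the programmed gamma-variate uptake; the first
# (pre-tracer) frame supplies the natural-abundance water reference, and
# voxels with glucose CRLB > 50% are dropped from the aggregate.
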