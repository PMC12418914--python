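"""Simulate a small kidney phantom acquisition and reconstruct it.

Builds a 10x10x8 two-compartment phantom, samples it on a concentric-ring
trajectory with 2 coils and correlated noise, reconstructs by adjoint
NUDFT, combines coils with WSVD and shows where the two deuterium
resonances land in the spectrum.
"""

import numpy as np

from dmipipe import (
    AcquisitionParams,
    Compartment,
    PhantomSpec,
    RelaxationAssumptions,
    adjoint_nudft,
    build_label_map,
    combine_image,
    estimate_noise_cov,
    fid_to_spectrum,
    make_crt_trajectory,
    simulate_fid_image,
)

acq = AcquisitionParams(matrix=(10, 10, 8), fov=(120.0, 120.0, 96.0), n_rings=8)
relax = RelaxationAssumptions()
hdo = relax.natural_hdo_mM

spec = PhantomSpec(
    matrix=acq.matrix,
    fov=acq.fov,
    compartments=[
        Compartment("abdomen", (0, 0, 0), (55, 45, 45), {"water": hdo},
                    linewidth_hz=15.0),
        Compartment("kidney", (18, 6, 0), (22, 22, 30),
                    {"water": hdo, "glc": 2.0}, linewidth_hz=14.0),
    ],
    noise_sd=10.0,
    seed=0,
)

labels = build_label_map(spec)
print("compartment voxel counts:", labels.counts)

traj = make_crt_trajectory(acq)
print(f"trajectory: {traj.ring_radii.size} rings, {traj.n_samples} in-plane "
      f"samples, {traj.n_kz} kz partitions")

ksp = simulate_fid_image(labels, spec, acq, relax, traj)
print("k-space shape (coil, kz, sample, time):", ksp.data.shape)

per_coil = adjoint_nudft(ksp, traj, acq)
cov = estimate_noise_cov(ksp.noise)
combined = combine_image(per_coil, cov)
spectrum = fid_to_spectrum(combined)

ix, iy, iz = np.argwhere(labels.mask("kidney"))[20]
voxel = np.abs(spectrum.data[ix, iy, iz])
ppm = spectrum.ppm_axis
water_region = np.abs(ppm - 4.8) < 0.4
glc_region = np.abs(ppm - 3.9) < 0.4
print("kidney-voxel peak near water:",
      round(float(ppm[water_region][np.argmax(voxel[water_region])]), 2), "ppm")
print("kidney-voxel peak near glucose:",
      round(float(ppm[glc_region][np.argmax(voxel[glc_region])]), 2), "ppm")
# Expected: ~4.8 ppm (water on the carrier) and ~3.9 ppm (glucose,
# -41.2 Hz at 7 T). Their amplitude ratio reflects concentration x
# deuteron count x steady-state saturation.
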