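"""Image reconstruction from concentric-ring k-space.

In-plane reconstruction is an adjoint non-uniform DFT with density
compensation (direct matrix evaluation; at matrices up to 28 x 28 this is
cheap and exact, which keeps the Cartesian-oracle equivalence trivial).
The kz direction is an ordinary inverse DFT over phase-encode partitions.
Spectra are obtained per voxel by FFT of the FID with optional exponential
apodization and zero-filling, plus a first-order phase ramp that removes
the phase accrued during the acquisition delay.
"""

from __future__ import annotations

import numpy as np

from .containers import KSpaceData, SpectralImage
from .params import AcquisitionParams
from .trajectory import Trajectory

__all__ = ["grid_coordinates_mm", "adjoint_nudft", "fid_to_spectrum"]


def grid_coordinates_mm(acq: AcquisitionParams):
    """Voxel-center coordinates (x, y, z) in mm, grid centered at the FOV
    center with index ``n//2`` at 0 (consistent forward and adjoint)."""
    coords = []
    for n, f in zip(acq.matrix, acq.fov):
        coords.append((np.arange(n) - n // 2) * (f / n))
    return tuple(coords)


def adjoint_nudft(
    ksp: KSpaceData, traj: Trajectory, acq: AcquisitionParams
) -> SpectralImage:
    """Adjoint NUDFT reconstruction onto the acquisition voxel grid.

    Evaluates ``rho(r, t) = (1/n_kz) * sum_k w_k d_k(t) exp(+i 2 pi k.r)``
    where the in-plane sum runs over the (density-weighted) ring samples and
    kz is handled as a standard inverse DFT over partitions. Output is a
    per-coil FID-domain :class:`SpectralImage` on ``acq.matrix``.
    """
    if ksp.n_samples != traj.n_samples:
        raise ValueError(
            f"k-space has {ksp.n_samples} in-plane samples, trajectory {traj.n_samples}"
        )
    if ksp.n_kz != traj.n_kz:
        raise ValueError("kz partition count mismatch between data and trajectory")

    nx, ny, nz = acq.matrix
    xs, ys, zs = grid_coordinates_mm(acq)
    n_coils, n_kz, ns, nt = ksp.data.shape

    # In-plane adjoint matrix (n_voxels_xy, n_samples)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    phase = gx.ravel()[:, None] * traj.kx[None, :] + gy.ravel()[:, None] * traj.ky[None, :]
    E = np.exp(2j * np.pi * phase)

    # kz adjoint (nz, n_kz), normalized so a point source keeps its amplitude
    Fz = np.exp(2j * np.pi * zs[:, None] * traj.kz_offsets[None, :]) / n_kz

    # quadrature scale: covered k-area times voxel area; equals 1 for the
    # degenerate Cartesian trajectory, ~pi/4 for the ring disk
    dx, dy = acq.voxel_size_mm[:2]
    area_scale = traj.k_area * dx * dy if traj.k_area else 1.0
    w = traj.weights * area_scale
    out = np.empty((n_coils, nx, ny, nz, nt), dtype=complex)
    for c in range(n_coils):
        wd = ksp.data[c] * w[None, :, None]          # (n_kz, ns, nt)
        # in-plane: (nxy, ns) @ (ns, n_kz*nt)
        img_xy = E @ wd.transpose(1, 0, 2).reshape(ns, n_kz * nt)
        img_xy = img_xy.reshape(nx, ny, n_kz, nt)
        # kz: contract partitions -> z
        out[c] = np.einsum("zp,xypt->xyzt", Fz, img_xy)

    return SpectralImage(data=out, domain="time", acq=acq, per_coil=True)


def fid_to_spectrum(
    img: SpectralImage,
    zerofill_factor: int = 1,
    apodization_hz: float = 0.0,
    correct_delay: bool = True,
) -> SpectralImage:
    """Transform per-voxel FIDs to spectra.

    Applies optional exponential (Lorentzian) apodization
    ``exp(-pi * lb * t)`` which adds ``lb`` Hz to every linewidth, zero-fills
    to ``zerofill_factor`` times the measured length, FFTs with the unitary
    ("ortho") convention, and removes the first-order phase ramp
    ``exp(i 2 pi f t_delay)`` accrued during the acquisition delay.
    """
    if img.domain != "time":
        raise ValueError("input image is already in the frequency domain")
    if zerofill_factor < 1:
        raise ValueError("zerofill_factor must be >= 1")

    n = img.data.shape[-1]
    dwell = img.acq.dwell_s
    fid = img.data
    if apodization_hz:
        t = np.arange(n) * dwell
        fid = fid * np.exp(-np.pi * apodization_hz * t)

    n_out = int(n * zerofill_factor)
    spec = np.fft.fft(fid, n=n_out, axis=-1, norm="ortho")
    spec = np.fft.fftshift(spec, axes=-1)
    freq = np.fft.fftshift(np.fft.fftfreq(n_out, d=dwell))

    if correct_delay and img.acq.acquisition_delay:
        delay_s = img.acq.acquisition_delay * 1e-3
        spec = spec * np.exp(-2j * np.pi * freq * delay_s)

    return img.copy_with(spec, domain="freq", freq_axis_hz=freq)
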