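"""Adjoint NUDFT reconstruction and FID-to-spectrum transform."""

import numpy as np
import pytest

from dmipipe import (
    AcquisitionParams,
    KSpaceData,
    SpectralImage,
    adjoint_nudft,
    fid_to_spectrum,
    make_crt_trajectory,
)
from dmipipe.recon import grid_coordinates_mm


def _cartesian_kspace_from_image(img, acq, traj):
    """Independent FFT-based forward model on the degenerate Cartesian grid.

    With the grid centered at index n//2, the forward sum over voxels equals
    fftshift(fftn(ifftshift(img))) — the numpy FFT is the oracle here.
    """
    D = np.fft.fftshift(
        np.fft.fftn(np.fft.ifftshift(img, axes=(0, 1, 2)), axes=(0, 1, 2)),
        axes=(0, 1, 2),
    )
    nx, ny, nz = acq.matrix
    nt = img.shape[-1]
    # traj sample order: meshgrid(ij) raveled -> (kx index, ky index)
    d = D.reshape(nx * ny, nz, nt).transpose(1, 0, 2)  # (kz, sample, t)
    return KSpaceData(data=d[None], noise=np.zeros((1, 64), complex), acq=acq)


def test_adjoint_matches_fft_inverse_on_cartesian_grid(acq_small):
    rng = np.random.default_rng(7)
    shape = acq_small.matrix + (acq_small.n_spectral_points,)
    img_true = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    traj = make_crt_trajectory(acq_small, degenerate_cartesian=True)
    ksp = _cartesian_kspace_from_image(img_true, acq_small, traj)
    rec = adjoint_nudft(ksp, traj, acq_small)
    rel = np.linalg.norm(rec.data[0] - img_true) / np.linalg.norm(img_true)
    assert rel <= 1e-10


def test_zero_kspace_gives_zero_image(acq_small):
    traj = make_crt_trajectory(acq_small)
    d = np.zeros((1, traj.n_kz, traj.n_samples, 4), complex)
    ksp = KSpaceData(data=d, noise=np.zeros((1, 64), complex), acq=acq_small)
    rec = adjoint_nudft(ksp, traj, acq_small)
    assert np.all(rec.data == 0)


def test_linearity_of_reconstruction(acq_small):
    rng = np.random.default_rng(3)
    traj = make_crt_trajectory(acq_small)
    shape = (1, traj.n_kz, traj.n_samples, 4)
    a = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    b = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    noise = np.zeros((1, 64), complex)
    ra = adjoint_nudft(KSpaceData(a, noise, acq_small), traj, acq_small)
    rb = adjoint_nudft(KSpaceData(b, noise, acq_small), traj, acq_small)
    rab = adjoint_nudft(KSpaceData(a + b, noise, acq_small), traj, acq_small)
    assert np.allclose(rab.data, ra.data + rb.data, atol=1e-12)


def test_point_source_psf_peaks_at_source_voxel(acq_small):
    traj = make_crt_trajectory(acq_small)
    xs, ys, zs = grid_coordinates_mm(acq_small)
    for vx, vy, vz in [(1, 2, 0), (4, 4, 2), (6, 1, 3)]:
        k2d = np.exp(-2j * np.pi * (traj.kx * xs[vx] + traj.ky * ys[vy]))
        kz = np.exp(-2j * np.pi * traj.kz_offsets * zs[vz])
        d = (kz[:, None] * k2d[None, :])[None, :, :, None].astype(complex)
        ksp = KSpaceData(d, np.zeros((1, 64), complex), acq_small)
        rec = adjoint_nudft(ksp, traj, acq_small)
        peak = np.unravel_index(
            np.argmax(np.abs(rec.data[0][..., 0])), acq_small.matrix
        )
        assert peak == (vx, vy, vz)


def test_dimension_mismatch_raises(acq_small):
    traj = make_crt_trajectory(acq_small)
    bad = np.zeros((1, traj.n_kz, traj.n_samples + 1, 4), complex)
    with pytest.raises(ValueError, match="samples"):
        adjoint_nudft(
            KSpaceData(bad, np.zeros((1, 64), complex), acq_small), traj, acq_small
        )


def test_smooth_object_amplitude_recovered(acq_default):
    """Density-compensated adjoint approximately inverts the forward model:
    NRMSE of a smooth object is well below the 15% bound."""
    traj = make_crt_trajectory(acq_default)
    xs, ys, zs = grid_coordinates_mm(acq_default)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    img = np.exp(
        -((gx - 20) ** 2 + (gy + 10) ** 2) / (2 * 45**2) - gz**2 / (2 * 50**2)
    )
    E = np.exp(
        -2j * np.pi * (
            traj.kx[:, None] * gx[..., 0].ravel()[None, :]
            + traj.ky[:, None] * gy[..., 0].ravel()[None, :]
        )
    )
    Fz = np.exp(-2j * np.pi * traj.kz_offsets[:, None] * zs[None, :])
    kzc = np.einsum("pz,xyz->xyp", Fz, img)
    d = (E @ kzc.reshape(len(xs) * len(ys), -1)).reshape(traj.n_samples, traj.n_kz).T
    ksp = KSpaceData(
        d[None, :, :, None].astype(complex), np.zeros((1, 64), complex), acq_default
    )
    rec = adjoint_nudft(ksp, traj, acq_default)
    r = np.abs(rec.data[0][..., 0])
    nrmse = np.linalg.norm(r - img) / np.linalg.norm(img)
    assert nrmse <= 0.15


# --- spectra ----------------------------------------------------------------


def _one_voxel_image(fid, acq):
    return SpectralImage(data=fid[None, None, None, :], domain="time", acq=acq)


def test_lorentzian_fwhm_matches_decay_rate():
    acq = AcquisitionParams(acquisition_delay=0.0)
    t2 = 0.0227  # ~14 Hz
    t = acq.time_axis_s()
    img = _one_voxel_image(np.exp(-t / t2).astype(complex), acq)
    spec = fid_to_spectrum(img, zerofill_factor=4)
    # FWHM of the absorption lineshape (real part of the phased spectrum);
    # the magnitude-mode width would be sqrt(3) wider
    absorption = spec.data[0, 0, 0].real
    half = absorption.max() / 2
    above = spec.freq_axis_hz[absorption >= half]
    fwhm = above.max() - above.min()
    assert fwhm == pytest.approx(1 / (np.pi * t2), rel=0.02)


def test_parseval_energy_conserved():
    acq = AcquisitionParams(acquisition_delay=0.0)
    rng = np.random.default_rng(11)
    fid = rng.standard_normal(acq.n_spectral_points) + 1j * rng.standard_normal(
        acq.n_spectral_points
    )
    spec = fid_to_spectrum(_one_voxel_image(fid, acq), zerofill_factor=1)
    assert np.sum(np.abs(fid) ** 2) == pytest.approx(
        np.sum(np.abs(spec.data[0, 0, 0]) ** 2), rel=1e-12
    )


def test_glucose_tone_lands_at_its_chemical_shift(acq_default):
    """A tone at the glucose offset (-41.2 Hz at 7 T) peaks at 3.9 ppm."""
    f_glc = acq_default.ppm_to_hz(3.9)
    assert f_glc == pytest.approx(-0.9 * 6.536 * 7.0, rel=1e-12)
    t = acq_default.time_axis_s()
    fid = np.exp(2j * np.pi * f_glc * t)
    spec = fid_to_spectrum(_one_voxel_image(fid, acq_default), zerofill_factor=4)
    peak_ppm = spec.ppm_axis[np.argmax(np.abs(spec.data[0, 0, 0]))]
    assert peak_ppm == pytest.approx(3.9, abs=0.03)


def test_frequency_domain_input_rejected(acq_small):
    img = SpectralImage(
        data=np.zeros(acq_small.matrix + (16,), complex),
        domain="freq",
        acq=acq_small,
        freq_axis_hz=np.arange(16.0),
    )
    with pytest.raises(ValueError, match="frequency domain"):
        fid_to_spectrum(img)
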