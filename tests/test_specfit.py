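"""Spectral fitting: parameter recovery, CRLB behavior, SNR and FWHM."""

import numpy as np
import pytest

from dmipipe import AcquisitionParams, BasisSet, Resonance, fit_voxel, snr_estimate
from dmipipe.containers import SpectralImage
from dmipipe.recon import fid_to_spectrum
from dmipipe.specfit import FitResult, fwhm_of_fit, noise_window_sd


@pytest.fixture
def acq():
    return AcquisitionParams()


def make_spectrum(acq, a_w=10.0, a_g=3.0, lw=14.0, phase=0.0, noise_sd=0.0,
                  rng=None):
    """Synthetic voxel spectrum through the same transform as the pipeline."""
    t = acq.time_axis_s()
    fw, fg = acq.ppm_to_hz(4.8), acq.ppm_to_hz(3.9)
    fid = (
        a_w * np.exp((2j * np.pi * fw - np.pi * lw) * t)
        + a_g * np.exp((2j * np.pi * fg - np.pi * lw) * t)
    ) * np.exp(1j * phase)
    img = SpectralImage(data=fid[None, None, None, :], domain="time", acq=acq)
    spec = fid_to_spectrum(img)
    data = spec.data[0, 0, 0].copy()
    if noise_sd:
        data = data + noise_sd * (
            rng.standard_normal(data.size) + 1j * rng.standard_normal(data.size)
        )
    return data, spec.freq_axis_hz


def test_noiseless_round_trip_recovers_all_parameters(acq):
    spec, freq = make_spectrum(acq, a_w=10.0, a_g=3.0, lw=14.0, phase=0.4)
    res = fit_voxel(spec, freq, BasisSet(), acq, noise_sd=0.01)
    assert res.converged
    assert res.amplitudes["water"] == pytest.approx(10.0, rel=0.01)
    assert res.amplitudes["glc"] == pytest.approx(3.0, rel=0.01)
    assert res.fwhm_hz["water"] == pytest.approx(14.0, rel=0.01)
    assert res.fwhm_hz["glc"] == pytest.approx(14.0, rel=0.01)
    assert res.phase0_rad == pytest.approx(0.4, abs=0.01)


def test_zero_glucose_is_flagged_by_crlb(acq):
    """With no glucose in the truth, the glucose CRLB exceeds the 50%
    exclusion threshold in nearly all noisy realizations."""
    rng = np.random.default_rng(0)
    flagged = 0
    n_trials = 50
    for _ in range(n_trials):
        spec, freq = make_spectrum(acq, a_w=10.0, a_g=0.0, noise_sd=0.5, rng=rng)
        res = fit_voxel(spec, freq, BasisSet(), acq)
        flagged += res.crlb_percent["glc"] > 50.0
    assert flagged >= 0.9 * n_trials


def test_halving_noise_halves_amplitude_crlb(acq):
    rng = np.random.default_rng(1)
    spec_hi, freq = make_spectrum(acq, noise_sd=1.0, rng=rng)
    spec_lo, _ = make_spectrum(acq, noise_sd=0.5, rng=rng)
    c_hi = fit_voxel(spec_hi, freq, BasisSet(), acq, noise_sd=1.0).crlb_percent
    c_lo = fit_voxel(spec_lo, freq, BasisSet(), acq, noise_sd=0.5).crlb_percent
    assert c_lo["water"] == pytest.approx(c_hi["water"] / 2, rel=0.10)


def test_amplitude_recovery_across_snr_and_linewidth_grid(acq):
    """Median absolute amplitude error < 5%, systematic bias < 2%."""
    rng = np.random.default_rng(2)
    errors = []
    for lw in (10.0, 14.0, 20.0):
        for noise_sd in (0.25, 0.6, 1.2):  # water SNR roughly 30 down to 6
            for _ in range(5):
                spec, freq = make_spectrum(
                    acq, a_w=10.0, a_g=3.0, lw=lw, noise_sd=noise_sd, rng=rng
                )
                res = fit_voxel(spec, freq, BasisSet(), acq)
                errors.append(res.amplitudes["water"] / 10.0 - 1.0)
    errors = np.array(errors)
    assert np.median(np.abs(errors)) < 0.05
    assert abs(np.mean(errors)) < 0.02


def test_crlb_is_calibrated_against_empirical_scatter(acq):
    """The reported CRLB tracks the true fit scatter: the ratio of the
    empirical SD of fitted amplitudes to the mean CRLB lies in [0.7, 1.6]."""
    rng = np.random.default_rng(3)
    amps, crlbs = [], []
    for _ in range(200):
        spec, freq = make_spectrum(acq, a_w=10.0, a_g=3.0, noise_sd=0.8, rng=rng)
        res = fit_voxel(spec, freq, BasisSet(), acq, noise_sd=0.8)
        amps.append(res.amplitudes["water"])
        crlbs.append(res.crlb_percent["water"] / 100 * res.amplitudes["water"])
    ratio = np.std(amps, ddof=1) / np.mean(crlbs)
    assert 0.7 <= ratio <= 1.6


class TestSNR:
    def test_zero_amplitude_gives_zero_snr(self, acq):
        rng = np.random.default_rng(4)
        spec, freq = make_spectrum(acq, a_w=0.0, a_g=0.0, noise_sd=1.0, rng=rng)
        assert snr_estimate(spec, freq, 0.0, [0.0, -41.2]) == 0.0

    def test_injected_peak_of_10_sigma_reads_snr_10(self, acq):
        rng = np.random.default_rng(5)
        n = acq.n_spectral_points
        freq = np.fft.fftshift(np.fft.fftfreq(n, d=acq.dwell_s))
        sigma = 1.0
        spec = sigma * (rng.standard_normal(n) + 1j * rng.standard_normal(n))
        peak_idx = np.argmin(np.abs(freq))
        spec[peak_idx] += 10.0 * sigma
        snr = snr_estimate(spec, freq, 10.0 * sigma, [0.0])
        assert snr == pytest.approx(10.0, rel=0.15)

    def test_snr_linear_in_amplitude_for_fixed_noise(self, acq):
        rng = np.random.default_rng(6)
        n = acq.n_spectral_points
        freq = np.fft.fftshift(np.fft.fftfreq(n, d=acq.dwell_s))
        spec = rng.standard_normal(n) + 1j * rng.standard_normal(n)
        s1 = snr_estimate(spec, freq, 5.0, [0.0])
        s2 = snr_estimate(spec, freq, 10.0, [0.0])
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    def test_empty_window_raises(self, acq):
        freq = np.linspace(-50, 50, 96)
        with pytest.raises(ValueError, match="min_offset"):
            noise_window_sd(np.zeros(96, complex), freq, [0.0])


class TestFWHM:
    def _fit(self, lw_l, lw_g=0.0):
        return FitResult(
            amplitudes={"water": 1.0}, freq_offsets_hz={"water": 0.0},
            fwhm_hz={"water": lw_l}, crlb_percent={"water": 1.0},
            phase0_rad=0.0, baseline=0j, gauss_fwhm_hz=lw_g, snr=1.0,
            residual_rms=0.0, converged=True, noise_sd=1.0,
        )

    def test_lorentzian_width_is_identity(self):
        assert fwhm_of_fit(self._fit(14.0), "water") == 14.0

    def test_pure_t2star_decay_width(self, acq):
        """A 36 ms decay constant corresponds to ~8.8 Hz FWHM; the fit
        recovers it from a synthetic spectrum."""
        lw_true = 1 / (np.pi * 0.036)
        spec, freq = make_spectrum(acq, a_w=10.0, a_g=0.0, lw=lw_true)
        res = fit_voxel(spec, freq, BasisSet(), acq, noise_sd=0.01)
        assert fwhm_of_fit(res, "water") == pytest.approx(8.84, abs=0.1)

    def test_voigt_reduces_to_lorentzian_without_gaussian_part(self):
        assert fwhm_of_fit(self._fit(14.0, 0.0), "water") == 14.0
        assert fwhm_of_fit(self._fit(14.0, 5.0), "water") > 14.0


def test_voigt_lineshape_fits_gaussian_broadened_line(acq):
    t = acq.time_axis_s()
    lw_g = 6.0
    fid = 10.0 * np.exp((2j * np.pi * 0.0 - np.pi * 10.0) * t) * np.exp(
        -((np.pi * lw_g * t) ** 2) / (4 * np.log(2))
    )
    img = SpectralImage(data=fid[None, None, None, :], domain="time", acq=acq)
    spec = fid_to_spectrum(img)
    basis = BasisSet(resonances=(Resonance("water", 4.8, 1),), lineshape="voigt")
    res = fit_voxel(spec.data[0, 0, 0], spec.freq_axis_hz, basis, acq, noise_sd=0.01)
    assert res.amplitudes["water"] == pytest.approx(10.0, rel=0.02)
    assert res.gauss_fwhm_hz == pytest.approx(lw_g, rel=0.05)


def test_duplicate_ppm_rejected():
    with pytest.raises(ValueError, match="distinct"):
        BasisSet(resonances=(Resonance("a", 4.8), Resonance("b", 4.8)))
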