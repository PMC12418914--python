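"""Digital phantom: voxelization, uptake curves, forward k-space model."""

import numpy as np
import pytest
from scipy import ndimage

from dmipipe import (
    AcquisitionParams,
    Compartment,
    PhantomSpec,
    RelaxationAssumptions,
    build_label_map,
    default_phantom_spec,
    make_crt_trajectory,
    simulate_fid_image,
    uptake_curve,
)
from conftest import mini_phantom


def _kidney_pair_spec():
    hdo = 13.9
    comps = [
        Compartment("kidney_left", (30.0, 0.0, 0.0), (18.0, 14.0, 20.0),
                    {"water": hdo}),
        Compartment("kidney_right", (-30.0, 0.0, 0.0), (18.0, 14.0, 20.0),
                    {"water": hdo}),
    ]
    return PhantomSpec(matrix=(20, 20, 16), fov=(120.0, 120.0, 96.0),
                       compartments=comps)


class TestLabelMap:
    def test_two_disjoint_kidneys_give_two_components(self):
        labels = build_label_map(_kidney_pair_spec())
        binary = labels.labels > 0
        _, n_components = ndimage.label(binary)
        assert n_components == 2
        assert set(labels.legend.values()) == {
            "background", "kidney_left", "kidney_right"
        }

    def test_no_compartments_gives_all_background(self):
        spec = PhantomSpec(matrix=(8, 8, 8), fov=(80.0, 80.0, 80.0))
        labels = build_label_map(spec)
        assert np.all(labels.labels == 0)

    def test_voxel_count_matches_analytic_ellipsoid_volume(self):
        # (30, 15, 15) mm semi-axes voxelized on a 3 mm grid
        spec = PhantomSpec(
            matrix=(40, 40, 40),
            fov=(120.0, 120.0, 120.0),
            compartments=[
                Compartment("blob", (0.0, 0.0, 0.0), (30.0, 15.0, 15.0),
                            {"water": 1.0})
            ],
        )
        labels = build_label_map(spec)
        count = labels.counts["blob"]
        analytic = 4 / 3 * np.pi * 30 * 15 * 15 / 27.0
        assert count == pytest.approx(analytic, rel=0.05)

    def test_later_compartment_overrides_earlier(self):
        spec = PhantomSpec(
            matrix=(10, 10, 10),
            fov=(100.0, 100.0, 100.0),
            compartments=[
                Compartment("outer", (0.0, 0.0, 0.0), (40.0, 40.0, 40.0), {}),
                Compartment("inner", (0.0, 0.0, 0.0), (15.0, 15.0, 15.0), {}),
            ],
        )
        labels = build_label_map(spec)
        center = labels.labels[5, 5, 5]
        assert labels.legend[center] == "inner"

    def test_geometry_outside_grid_raises_with_name(self):
        spec = PhantomSpec(
            matrix=(10, 10, 10),
            fov=(100.0, 100.0, 100.0),
            compartments=[
                Compartment("stray", (500.0, 0.0, 0.0), (10.0, 10.0, 10.0), {})
            ],
        )
        with pytest.raises(ValueError, match="stray"):
            build_label_map(spec)


class TestUptakeCurve:
    def test_saturating_limits(self):
        p = {"C0": 1.0, "dC": 1.8, "tau": 10.0}
        assert uptake_curve("saturating", p, [0.0])[0] == pytest.approx(1.0)
        assert uptake_curve("saturating", p, [100.0])[0] == pytest.approx(
            2.8, rel=0.01
        )

    def test_gamma_variate_peaks_at_tp_with_value_c0_plus_a(self):
        p = {"C0": 0.5, "A": 2.0, "t_p": 37.0, "alpha": 2.0}
        t = np.linspace(0, 120, 4801)
        c = uptake_curve("gamma_variate", p, t)
        assert t[np.argmax(c)] == pytest.approx(37.0, abs=0.05)
        assert c.max() == pytest.approx(2.5, rel=1e-4)

    def test_constant_kind(self):
        assert np.all(uptake_curve("constant", {"C0": 3.0}, [0, 5, 10]) == 3.0)

    def test_unknown_kind_and_negative_params_raise(self):
        with pytest.raises(ValueError, match="unknown"):
            uptake_curve("sigmoid", {}, [0.0])
        with pytest.raises(ValueError):
            uptake_curve("saturating", {"C0": 1.0, "dC": -1.0, "tau": 5.0}, [0.0])


class TestForwardModel:
    def test_zero_concentration_gives_pure_noise_at_stated_sd(self, acq_mini, relax):
        spec = mini_phantom(acq_mini, relax, noise_sd=2.5, seed=4)
        for comp in spec.compartments:
            comp.concentrations_mM = {"water": 0.0, "glc": 0.0}
            comp.uptake = {}
        labels = build_label_map(spec)
        traj = make_crt_trajectory(acq_mini)
        ksp = simulate_fid_image(labels, spec, acq_mini, relax, traj)
        sample = ksp.data.ravel()[:10000]
        assert np.std(sample.real) == pytest.approx(2.5, rel=0.05)
        assert np.std(sample.imag) == pytest.approx(2.5, rel=0.05)

    def test_point_source_has_constant_kspace_modulus(self, relax):
        acq = AcquisitionParams(
            matrix=(10, 10, 8), fov=(120.0, 120.0, 96.0),
            n_spectral_points=8, n_rings=8,
        )
        # ellipsoid smaller than a voxel centered on a voxel center
        spec = PhantomSpec(
            matrix=acq.matrix, fov=acq.fov, n_coils=1, noise_sd=0.0,
            compartments=[
                Compartment("dot", (12.0, -24.0, 12.0), (4.0, 4.0, 4.0),
                            {"water": 10.0})
            ],
        )
        labels = build_label_map(spec)
        assert labels.counts["dot"] == 1
        traj = make_crt_trajectory(acq)
        ksp = simulate_fid_image(labels, spec, acq, relax, traj, add_noise=False)
        for it in (0, 3, 7):
            mags = np.abs(ksp.data[0, :, :, it])
            assert np.allclose(mags, mags.flat[0], rtol=1e-12)

    def test_forward_model_linear_in_concentration(self, acq_mini, relax):
        spec = mini_phantom(acq_mini, relax, noise_sd=0.0, seed=0)
        labels = build_label_map(spec)
        traj = make_crt_trajectory(acq_mini)
        k1 = simulate_fid_image(labels, spec, acq_mini, relax, traj,
                                time_min=37.0, add_noise=False)
        for comp in spec.compartments:
            comp.concentrations_mM = {
                m: 2 * v for m, v in comp.concentrations_mM.items()
            }
            if "glc" in comp.uptake:
                kind, p = comp.uptake["glc"]
                p = dict(p)
                p["A"] *= 2
                p["C0"] *= 2
                comp.uptake["glc"] = (kind, p)
        k2 = simulate_fid_image(labels, spec, acq_mini, relax, traj,
                                time_min=37.0, add_noise=False)
        assert np.allclose(k2.data, 2 * k1.data, rtol=1e-12)

    def test_identical_seed_gives_bit_identical_kspace(self, acq_mini, relax):
        spec = mini_phantom(acq_mini, relax, noise_sd=1.0, seed=9)
        labels = build_label_map(spec)
        traj = make_crt_trajectory(acq_mini)
        a = simulate_fid_image(labels, spec, acq_mini, relax, traj, frame_index=2)
        b = simulate_fid_image(labels, spec, acq_mini, relax, traj, frame_index=2)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.noise, b.noise)

    def test_grid_mismatch_raises(self, acq_mini, relax):
        spec = mini_phantom(acq_mini, relax)
        labels = build_label_map(spec)
        other = AcquisitionParams(matrix=(8, 8, 4), fov=(80.0, 80.0, 40.0),
                                  n_rings=5)
        traj = make_crt_trajectory(other)
        with pytest.raises(ValueError):
            simulate_fid_image(labels, spec, other, relax, traj)

    def test_resonance_separation_is_41hz_at_7t(self, acq_default):
        sep = acq_default.ppm_to_hz(4.8) - acq_default.ppm_to_hz(3.9)
        assert sep == pytest.approx(0.9 * 6.536 * 7.0, rel=1e-12)
        assert sep == pytest.approx(41.2, abs=0.1)


def test_default_phantom_spec_roundtrips_through_yaml(tmp_path):
    spec = default_phantom_spec()
    path = tmp_path / "phantom.yaml"
    spec.to_yaml(path)
    loaded = PhantomSpec.from_yaml(path)
    assert loaded.matrix == spec.matrix
    assert [c.label for c in loaded.compartments] == [
        c.label for c in spec.compartments
    ]
    assert loaded.compartments[1].uptake["glc"][0] == "gamma_variate"
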