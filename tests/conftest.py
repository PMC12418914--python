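"""Shared fixtures: small acquisition grids and phantoms built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from dmipipe import (
    AcquisitionParams,
    Compartment,
    PhantomSpec,
    RelaxationAssumptions,
)


@pytest.fixture
def acq_small() -> AcquisitionParams:
    """8x8x4 grid, 16 FID points — oracle-scale acquisition."""
    return AcquisitionParams(
        matrix=(8, 8, 4), fov=(80.0, 80.0, 40.0), n_spectral_points=16, n_rings=5
    )


@pytest.fixture
def acq_default() -> AcquisitionParams:
    """The 1.8 mL protocol: 22x22x21, 47 rings, 96 points at 380 Hz."""
    return AcquisitionParams()


@pytest.fixture
def relax() -> RelaxationAssumptions:
    return RelaxationAssumptions()


@pytest.fixture
def acq_mini() -> AcquisitionParams:
    """10x10x8 grid for fast end-to-end runs."""
    return AcquisitionParams(
        matrix=(10, 10, 8), fov=(120.0, 120.0, 96.0), n_spectral_points=96, n_rings=8
    )


def mini_phantom(
    acq: AcquisitionParams,
    relax: RelaxationAssumptions,
    noise_sd: float = 0.0,
    seed: int = 0,
    water_uptake=None,
    glc_peak_mM: float = 2.0,
) -> PhantomSpec:
    """Small two-compartment phantom (body + one kidney) on a mini grid."""
    hdo = relax.natural_hdo_mM
    kidney = Compartment(
        label="kidney_left",
        center_mm=(18.0, 6.0, 0.0),
        semi_axes_mm=(22.0, 22.0, 30.0),
        concentrations_mM={"water": hdo, "glc": 0.0},
        linewidth_hz=14.0,
        uptake={
            "glc": (
                "gamma_variate",
                {"C0": 0.0, "A": glc_peak_mM, "t_p": 37.0, "alpha": 2.0},
            )
        },
    )
    if water_uptake is not None:
        kidney.uptake["water"] = water_uptake
    body = Compartment(
        label="abdomen",
        center_mm=(0.0, 0.0, 0.0),
        semi_axes_mm=(55.0, 45.0, 45.0),
        concentrations_mM={"water": hdo, "glc": 0.0},
        linewidth_hz=15.0,
    )
    return PhantomSpec(
        matrix=acq.matrix,
        fov=acq.fov,
        compartments=[body, kidney],
        noise_sd=noise_sd,
        seed=seed,
    )
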