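"""Acquisition and relaxation parameter containers.

The defaults reproduce a 7 T renal deuterium MRSI protocol: FID-MRSI with a
concentric-ring readout, TR 290 ms, 380 Hz spectral bandwidth, 96 spectral
points, 2.0 ms acquisition delay, a 270 x 270 x 260 mm^3 field of view and a
22 x 22 x 21 (~1.8 mL) or 28 x 28 x 27 (~0.9 mL) matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Tuple

import numpy as np
import yaml

__all__ = ["AcquisitionParams", "RelaxationAssumptions", "WATER_PPM", "GLC_PPM"]

#: Chemical shifts of the two deuterated resonances (ppm).
WATER_PPM = 4.8
GLC_PPM = 3.9

#: Molar concentration of pure water (mM), 2 hydrogen sites per molecule.
WATER_MOLARITY_MM = 55_510.0


@dataclass(frozen=True)
class AcquisitionParams:
    """Timing, geometry and field constants of the 2H-MRSI acquisition.

    Parameters
    ----------
    field_strength : float
        Static field B0 in tesla.
    gamma_2H : float
        Gyromagnetic ratio of deuterium in MHz/T.
    TR : float
        Repetition time in ms.
    flip_angle : float
        Excitation flip angle in degrees (67 or 90 in the target protocol).
    acquisition_delay : float
        Dead time between excitation and the first FID sample, ms.
    spectral_bandwidth : float
        Readout (spectral) bandwidth in Hz; dwell time is its inverse.
    n_spectral_points : int
        Number of complex FID points per readout.
    fov : tuple of float
        Field of view (x, y, z) in mm.
    matrix : tuple of int
        Nominal image matrix (nx, ny, nz).
    n_rings : int
        Number of concentric k-space rings per kz partition.
    reference_ppm : float
        Chemical shift of the carrier frequency; water sits on resonance.
    """

    field_strength: float = 7.0
    gamma_2H: float = 6.536
    TR: float = 290.0
    flip_angle: float = 90.0
    acquisition_delay: float = 2.0
    spectral_bandwidth: float = 380.0
    n_spectral_points: int = 96
    fov: Tuple[float, float, float] = (270.0, 270.0, 260.0)
    matrix: Tuple[int, int, int] = (22, 22, 21)
    n_rings: int = 47
    reference_ppm: float = 4.8

    def __post_init__(self) -> None:
        scalars = {
            "field_strength": self.field_strength,
            "gamma_2H": self.gamma_2H,
            "TR": self.TR,
            "flip_angle": self.flip_angle,
            "spectral_bandwidth": self.spectral_bandwidth,
            "n_rings": self.n_rings,
            "reference_ppm": self.reference_ppm,
        }
        for name, value in scalars.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.acquisition_delay < 0:
            raise ValueError("acquisition_delay must be non-negative")
        if self.n_spectral_points < 2:
            raise ValueError("n_spectral_points must be >= 2")
        if any(m < 2 for m in self.matrix):
            raise ValueError("matrix entries must be >= 2")
        if any(f <= 0 for f in self.fov):
            raise ValueError("fov entries must be positive")
        object.__setattr__(self, "fov", tuple(float(f) for f in self.fov))
        object.__setattr__(self, "matrix", tuple(int(m) for m in self.matrix))

    # --- derived quantities -------------------------------------------------

    @property
    def dwell_s(self) -> float:
        """Dwell time between FID samples in seconds (1/spectral bandwidth)."""
        return 1.0 / self.spectral_bandwidth

    @property
    def carrier_mhz(self) -> float:
        """Deuterium Larmor frequency gamma * B0 in MHz (Hz per ppm)."""
        return self.gamma_2H * self.field_strength

    def ppm_to_hz(self, ppm: float | np.ndarray) -> float | np.ndarray:
        """Frequency offset from the carrier, Hz, of a resonance at ``ppm``."""
        return (np.asarray(ppm) - self.reference_ppm) * self.carrier_mhz

    def hz_to_ppm(self, hz: float | np.ndarray) -> float | np.ndarray:
        """Inverse of :meth:`ppm_to_hz`."""
        return self.reference_ppm + np.asarray(hz) / self.carrier_mhz

    @property
    def voxel_size_mm(self) -> Tuple[float, float, float]:
        """Nominal voxel edge lengths FOV/matrix in mm."""
        return tuple(f / m for f, m in zip(self.fov, self.matrix))

    @property
    def voxel_volume_ml(self) -> float:
        """Nominal voxel volume in mL (exact, rounding left to display code)."""
        return float(np.prod(self.voxel_size_mm)) / 1000.0

    def time_axis_s(self, include_delay: bool = True) -> np.ndarray:
        """FID sample times in seconds, starting at the acquisition delay."""
        t = np.arange(self.n_spectral_points) * self.dwell_s
        if include_delay:
            t = t + self.acquisition_delay * 1e-3
        return t

    # --- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fov"] = list(self.fov)
        d["matrix"] = list(self.matrix)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionParams":
        d = dict(d)
        if "fov" in d:
            d["fov"] = tuple(d["fov"])
        if "matrix" in d:
            d["matrix"] = tuple(d["matrix"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AcquisitionParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass(frozen=True)
class RelaxationAssumptions:
    """Relaxation times and referencing constants assumed for quantification.

    No 2H relaxation times have been reported for human kidney at 7 T, so
    brain-tissue values are assumed: T1 335/70 ms and T2 36/36 ms for
    water/glucose, with an 80% tissue water content. ``n_labels_*`` counts the
    deuterons per molecule (HDO carries 1, [6,6']-2H-glucose carries 2).
    """

    T1_water: float = 335.0
    T1_glc: float = 70.0
    T2_water: float = 36.0
    T2_glc: float = 36.0
    water_content_fraction: float = 0.80
    n_labels_water: int = 1
    n_labels_glc: int = 2
    natural_abundance_fraction: float = 1.56e-4

    def __post_init__(self) -> None:
        for name in ("T1_water", "T1_glc", "T2_water", "T2_glc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.water_content_fraction <= 1:
            raise ValueError("water_content_fraction must be in (0, 1]")
        if self.n_labels_water < 1 or self.n_labels_glc < 1:
            raise ValueError("label counts must be >= 1")
        if not 0 <= self.natural_abundance_fraction < 1:
            raise ValueError("natural_abundance_fraction must be in [0, 1)")

    @property
    def natural_hdo_mM(self) -> float:
        """Natural-abundance HDO reference concentration in tissue, mM.

        Each water molecule has two hydrogen sites, each deuterated with
        probability equal to the natural abundance, and only the tissue
        water fraction contributes: 2 * f_NA * 55510 mM * water content
        (~13.9 mM at defaults).
        """
        return (
            2.0
            * self.natural_abundance_fraction
            * WATER_MOLARITY_MM
            * self.water_content_fraction
        )

    def t1_of(self, metabolite: str) -> float:
        return {"water": self.T1_water, "glc": self.T1_glc}[metabolite]

    def t2_of(self, metabolite: str) -> float:
        return {"water": self.T2_water, "glc": self.T2_glc}[metabolite]

    def n_labels_of(self, metabolite: str) -> int:
        return {"water": self.n_labels_water, "glc": self.n_labels_glc}[metabolite]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RelaxationAssumptions":
        return cls(**d)
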