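"""Digital kidney phantom and multi-coil CRT k-space simulation.

The phantom is a voxelized set of ellipsoidal compartments (an abdominal
body, two kidneys, and an optional anterior "stomach" region emulating
tracer pooling in the gastrointestinal tract). Each compartment carries
baseline concentrations and uptake curves for the two deuterated
resonances — water (4.8 ppm) and glucose (3.9 ppm) — and a Lorentzian
linewidth that sets the voxel T2*.

The forward model imposes steady-state amplitudes analytically (no Bloch
simulation): the FID of voxel r is

    rho(r, t) = sum_m A_m(r) exp(i 2 pi f_m t) exp(-pi lw(r) t) exp(i phi0)

with f_m = (ppm_m - reference_ppm) * gamma * B0 and A_m proportional to
concentration x deuterons per molecule x Ernst saturation factor. k-space
samples per coil are the exact (non-uniform) Fourier sums of the
sensitivity-weighted voxel signal, with correlated complex Gaussian noise
and a matching noise-only reference block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .containers import KSpaceData, SpectralImage
from .params import AcquisitionParams, RelaxationAssumptions, WATER_PPM, GLC_PPM
from .quantify import saturation_factor
from .recon import grid_coordinates_mm
from .trajectory import Trajectory

__all__ = [
    "Compartment",
    "PhantomSpec",
    "LabelMap",
    "build_label_map",
    "uptake_curve",
    "coil_sensitivities",
    "amplitude_maps",
    "ground_truth_fid_image",
    "simulate_fid_image",
    "default_phantom_spec",
]

METABOLITE_PPM = {"water": WATER_PPM, "glc": GLC_PPM}


@dataclass
class Compartment:
    """Ellipsoidal tissue compartment.

    ``uptake`` maps metabolite name to ``(kind, params)`` where kind is one
    of "constant", "saturating", "gamma_variate" (see :func:`uptake_curve`);
    metabolites absent from ``uptake`` stay at their baseline concentration.
    """

    label: str
    center_mm: Tuple[float, float, float]
    semi_axes_mm: Tuple[float, float, float]
    concentrations_mM: Dict[str, float]
    linewidth_hz: float = 14.0
    uptake: Dict[str, Tuple[str, Dict[str, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.linewidth_hz <= 0:
            raise ValueError(f"compartment {self.label}: linewidth must be > 0")

    def concentration(self, metabolite: str, time_min: float) -> float:
        base = self.concentrations_mM.get(metabolite, 0.0)
        if metabolite in self.uptake:
            kind, params = self.uptake[metabolite]
            return float(uptake_curve(kind, params, np.atleast_1d(time_min))[0])
        return base


@dataclass
class PhantomSpec:
    """Full phantom description: geometry, dynamics, coils and noise.

    ``noise_sd`` is the standard deviation of the real and imaginary parts
    of the per-sample complex noise on each channel; ``noise_correlation``
    the correlation coefficient between channels (a butterfly + loop pair
    is not independent).
    """

    matrix: Tuple[int, int, int] = (22, 22, 21)
    fov: Tuple[float, float, float] = (270.0, 270.0, 260.0)
    compartments: List[Compartment] = field(default_factory=list)
    n_coils: int = 2
    coil_depth_mm: float = 180.0
    coil_positions_mm: Optional[Sequence[Tuple[float, float, float]]] = None
    noise_sd: float = 0.0
    noise_correlation: float = 0.2
    phi0: float = 0.0
    b0_offset_hz: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not -1 < self.noise_correlation < 1:
            raise ValueError("noise_correlation must be in (-1, 1)")
        if self.n_coils < 1:
            raise ValueError("n_coils must be >= 1")

    @property
    def voxel_size_mm(self) -> Tuple[float, float, float]:
        return tuple(f / m for f, m in zip(self.fov, self.matrix))

    def to_dict(self) -> dict:
        d = {
            "matrix": list(self.matrix),
            "fov": list(self.fov),
            "n_coils": self.n_coils,
            "coil_depth_mm": self.coil_depth_mm,
            "noise_sd": self.noise_sd,
            "noise_correlation": self.noise_correlation,
            "phi0": self.phi0,
            "seed": self.seed,
            "compartments": [
                {
                    "label": c.label,
                    "center_mm": list(c.center_mm),
                    "semi_axes_mm": list(c.semi_axes_mm),
                    "concentrations_mM": dict(c.concentrations_mM),
                    "linewidth_hz": c.linewidth_hz,
                    "uptake": {
                        m: [kind, dict(params)] for m, (kind, params) in c.uptake.items()
                    },
                }
                for c in self.compartments
            ],
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        comps = []
        for cd in d.pop("compartments", []):
            cd = dict(cd)
            cd["center_mm"] = tuple(cd["center_mm"])
            cd["semi_axes_mm"] = tuple(cd["semi_axes_mm"])
            cd["uptake"] = {
                m: (kind, dict(params))
                for m, (kind, params) in (cd.get("uptake") or {}).items()
            }
            comps.append(Compartment(**cd))
        if "matrix" in d:
            d["matrix"] = tuple(d["matrix"])
        if "fov" in d:
            d["fov"] = tuple(d["fov"])
        return cls(compartments=comps, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class LabelMap:
    """Integer label volume with legend; label 0 is background."""

    labels: np.ndarray
    legend: Dict[int, str]

    @property
    def counts(self) -> Dict[str, int]:
        return {
            name: int((self.labels == idx).sum()) for idx, name in self.legend.items()
        }

    def mask(self, name: str) -> np.ndarray:
        for idx, label in self.legend.items():
            if label == name:
                return self.labels == idx
        raise KeyError(name)


def _grid_mm(spec: PhantomSpec):
    coords = []
    for n, f in zip(spec.matrix, spec.fov):
        coords.append((np.arange(n) - n // 2) * (f / n))
    return np.meshgrid(*coords, indexing="ij")


def build_label_map(spec: PhantomSpec) -> LabelMap:
    """Voxelize compartments (voxel center-in-ellipsoid test).

    Later-listed compartments override earlier ones where they overlap.
    A compartment whose ellipsoid contains no voxel center raises an error
    naming it.
    """
    gx, gy, gz = _grid_mm(spec)
    labels = np.zeros(spec.matrix, dtype=np.int16)
    legend = {0: "background"}
    for i, comp in enumerate(spec.compartments, start=1):
        cx, cy, cz = comp.center_mm
        ax, ay, az = comp.semi_axes_mm
        inside = (
            ((gx - cx) / ax) ** 2 + ((gy - cy) / ay) ** 2 + ((gz - cz) / az) ** 2
        ) <= 1.0
        if not inside.any():
            raise ValueError(
                f"compartment {comp.label!r} lies outside the phantom grid"
            )
        labels[inside] = i
        legend[i] = comp.label
    return LabelMap(labels=labels, legend=legend)


def uptake_curve(kind: str, params: Dict[str, float], times_min) -> np.ndarray:
    """Tracer concentration time course in mM.

    kinds:
      - ``constant``: C(t) = C0
      - ``saturating``: C(t) = C0 + dC (1 - exp(-t/tau))
      - ``gamma_variate``: C(t) = C0 + A (t/t_p)^alpha exp(alpha (1 - t/t_p)),
        which peaks at t = t_p with peak value C0 + A.
    """
    t = np.asarray(times_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if t.ndim and np.any(np.diff(t) < 0):
        raise ValueError("times must be non-decreasing")
    for key, value in params.items():
        if value < 0:
            raise ValueError(f"uptake parameter {key} must be non-negative")
    if kind == "constant":
        return np.full_like(t, params.get("C0", 0.0))
    if kind == "saturating":
        c0, dc, tau = params.get("C0", 0.0), params["dC"], params["tau"]
        return c0 + dc * (1.0 - np.exp(-t / tau))
    if kind == "gamma_variate":
        c0, a = params.get("C0", 0.0), params["A"]
        tp, alpha = params["t_p"], params.get("alpha", 2.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            curve = (t / tp) ** alpha * np.exp(alpha * (1.0 - t / tp))
        curve = np.where(t > 0, curve, 0.0)
        return c0 + a * curve
    raise ValueError(f"unknown uptake-curve kind {kind!r}")


def coil_sensitivities(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Complex coil-sensitivity maps, shape (n_coils, nx, ny, nz).

    Biot-Savart-like falloff from posterior coil centers (the array sits
    behind the supine subject, +y): |s| = 1 / (1 + (d/depth)^2) with d the
    distance to the coil center; per-coil constant phases are drawn from the
    seeded generator.
    """
    gx, gy, gz = _grid_mm(spec)
    if spec.coil_positions_mm is not None:
        positions = list(spec.coil_positions_mm)
    else:
        ymax = spec.fov[1] / 2.0
        offsets = np.linspace(-spec.fov[0] / 4.0, spec.fov[0] / 4.0, spec.n_coils)
        positions = [(float(dx), float(ymax), 0.0) for dx in offsets]
    phases = rng.uniform(-np.pi, np.pi, size=spec.n_coils)
    maps = np.empty((spec.n_coils,) + tuple(spec.matrix), dtype=complex)
    for c, (px, py, pz) in enumerate(positions):
        d2 = (gx - px) ** 2 + (gy - py) ** 2 + (gz - pz) ** 2
        mag = 1.0 / (1.0 + d2 / spec.coil_depth_mm**2)
        maps[c] = mag * np.exp(1j * phases[c])
    return maps


def amplitude_maps(
    labels: LabelMap,
    spec: PhantomSpec,
    acq: AcquisitionParams,
    relax: RelaxationAssumptions,
    time_min: float = 0.0,
) -> Dict[str, np.ndarray]:
    """Per-metabolite signal amplitude maps at a given time point.

    A_m(r) = C_m(r) * n_labels_m * Ernst saturation factor for metabolite m.
    """
    out: Dict[str, np.ndarray] = {}
    for met in METABOLITE_PPM:
        amp = np.zeros(spec.matrix)
        sat = saturation_factor(acq.TR, relax.t1_of(met), acq.flip_angle)
        for i, comp in enumerate(spec.compartments, start=1):
            conc = comp.concentration(met, time_min)
            if conc:
                amp[labels.labels == i] = conc * relax.n_labels_of(met) * sat
        out[met] = amp
    return out


def linewidth_map(labels: LabelMap, spec: PhantomSpec) -> np.ndarray:
    """Per-voxel Lorentzian linewidth (Hz); background gets 14 Hz (unused)."""
    lw = np.full(spec.matrix, 14.0)
    for i, comp in enumerate(spec.compartments, start=1):
        lw[labels.labels == i] = comp.linewidth_hz
    return lw


def ground_truth_fid_image(
    labels: LabelMap,
    spec: PhantomSpec,
    acq: AcquisitionParams,
    relax: RelaxationAssumptions,
    time_min: float = 0.0,
    include_delay: bool = True,
) -> SpectralImage:
    """Noiseless, coil-free voxel FID cube (the pipeline's ground truth)."""
    amps = amplitude_maps(labels, spec, acq, relax, time_min)
    lw = linewidth_map(labels, spec)
    t = acq.time_axis_s(include_delay=include_delay)
    data = np.zeros(tuple(spec.matrix) + (acq.n_spectral_points,), dtype=complex)
    decay = np.exp(-np.pi * lw[..., None] * t[None, None, None, :])
    b0 = spec.b0_offset_hz
    for met, ppm in METABOLITE_PPM.items():
        f = acq.ppm_to_hz(ppm)
        if b0 is not None:
            osc = np.exp(2j * np.pi * (f + b0)[..., None] * t)
        else:
            osc = np.exp(2j * np.pi * f * t)[None, None, None, :]
        data += amps[met][..., None] * osc * decay
    data *= np.exp(1j * spec.phi0)
    return SpectralImage(data=data, domain="time", acq=acq, per_coil=False)


def _correlated_noise(
    rng: np.random.Generator, sd: float, corr: float, n_coils: int, shape
) -> np.ndarray:
    """Complex Gaussian noise, per-component SD ``sd``, inter-channel
    correlation ``corr`` (same for real and imaginary parts)."""
    cov = np.full((n_coils, n_coils), corr) + (1.0 - corr) * np.eye(n_coils)
    L = np.linalg.cholesky(cov)
    size = (n_coils,) + tuple(shape)
    re = rng.standard_normal(size)
    im = rng.standard_normal(size)
    white = re + 1j * im
    return sd * np.einsum("ij,j...->i...", L, white)


def simulate_fid_image(
    labels: LabelMap,
    spec: PhantomSpec,
    acq: AcquisitionParams,
    relax: RelaxationAssumptions,
    traj: Trajectory,
    time_min: float = 0.0,
    frame_index: int = 0,
    add_noise: bool = True,
    n_noise_samples: int = 4096,
) -> KSpaceData:
    """Simulate the multi-coil CRT k-space acquisition of one time frame.

    The k-space sample of coil c at (kx, ky, kz, t) is the exact Fourier sum
    ``sum_r s_c(r) rho(r, t) exp(-i 2 pi k . r)`` over voxel centers, with
    the kz direction a Cartesian phase-encode DFT. Correlated complex
    Gaussian noise and a matching noise-only block are generated from a
    generator seeded by (spec.seed, frame_index), so identical inputs give
    bit-identical output.
    """
    if tuple(spec.matrix) != tuple(acq.matrix) or tuple(spec.fov) != tuple(acq.fov):
        raise ValueError("phantom grid and acquisition grid differ")
    if traj.n_kz != acq.matrix[2]:
        raise ValueError("trajectory kz partitions do not match acquisition matrix")
    traj.validate(acq)

    # coil geometry/phases are fixed across frames; only noise varies per frame
    sens = coil_sensitivities(spec, np.random.default_rng(spec.seed))
    rng = np.random.default_rng([spec.seed, 1 + frame_index])

    gt = ground_truth_fid_image(labels, spec, acq, relax, time_min)
    nx, ny, nz = acq.matrix
    nt = acq.n_spectral_points
    ns = traj.n_samples
    xs, ys, zs = grid_coordinates_mm(acq)

    # Forward in-plane NUDFT matrix (ns, nxy) and kz phase-encode DFT (n_kz, nz)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    E = np.exp(
        -2j
        * np.pi
        * (traj.kx[:, None] * gx.ravel()[None, :] + traj.ky[:, None] * gy.ravel()[None, :])
    )
    Fz = np.exp(-2j * np.pi * traj.kz_offsets[:, None] * zs[None, :])

    data = np.empty((spec.n_coils, traj.n_kz, ns, nt), dtype=complex)
    for c in range(spec.n_coils):
        vox = sens[c][..., None] * gt.data                      # (nx,ny,nz,nt)
        kz_cube = np.einsum("pz,xyzt->xypt", Fz, vox)            # (nx,ny,n_kz,nt)
        flat = kz_cube.reshape(nx * ny, traj.n_kz * nt)
        samples = E @ flat                                       # (ns, n_kz*nt)
        data[c] = samples.reshape(ns, traj.n_kz, nt).transpose(1, 0, 2)

    if add_noise and spec.noise_sd > 0:
        data += _correlated_noise(
            rng, spec.noise_sd, spec.noise_correlation, spec.n_coils,
            (traj.n_kz, ns, nt),
        )
    noise_block = _correlated_noise(
        rng, spec.noise_sd, spec.noise_correlation, spec.n_coils, (n_noise_samples,)
    ) if spec.noise_sd > 0 else np.zeros((spec.n_coils, n_noise_samples), dtype=complex)

    return KSpaceData(data=data, noise=noise_block, acq=acq)


def default_phantom_spec(
    matrix: Tuple[int, int, int] = (22, 22, 21),
    fov: Tuple[float, float, float] = (270.0, 270.0, 260.0),
    relax: RelaxationAssumptions | None = None,
    glucose_peak_mM: float = 2.0,
    glucose_peak_min: float = 37.0,
    include_stomach: bool = False,
    noise_sd: float = 200.0,
    seed: int = 0,
) -> PhantomSpec:
    """Abdomen + two-kidney phantom with a dynamic renal glucose uptake.

    Baseline water everywhere in the body is the natural-abundance HDO
    level (~13.9 mM at an 80% water content); renal glucose follows a
    gamma-variate peaking at ``glucose_peak_mM`` (~2 mM, the scale seen in
    vivo) ``glucose_peak_min`` minutes after tracer intake. The optional anterior
    stomach compartment carries a strong early glucose signal emulating
    gastrointestinal pooling.
    """
    relax = relax or RelaxationAssumptions()
    hdo = relax.natural_hdo_mM
    glc_uptake = (
        "gamma_variate",
        {"C0": 0.0, "A": glucose_peak_mM, "t_p": glucose_peak_min, "alpha": 2.0},
    )
    compartments = [
        Compartment(
            label="abdomen",
            center_mm=(0.0, 0.0, 0.0),
            semi_axes_mm=(128.0, 100.0, 124.0),
            concentrations_mM={"water": hdo, "glc": 0.0},
            linewidth_hz=15.0,
        ),
        Compartment(
            label="kidney_left",
            center_mm=(65.0, 35.0, 0.0),
            semi_axes_mm=(28.0, 22.0, 55.0),
            concentrations_mM={"water": hdo, "glc": 0.0},
            linewidth_hz=14.0,
            uptake={"glc": glc_uptake},
        ),
        Compartment(
            label="kidney_right",
            center_mm=(-65.0, 35.0, 0.0),
            semi_axes_mm=(28.0, 22.0, 55.0),
            concentrations_mM={"water": hdo, "glc": 0.0},
            linewidth_hz=14.0,
            uptake={"glc": glc_uptake},
        ),
    ]
    if include_stomach:
        compartments.append(
            Compartment(
                label="stomach",
                center_mm=(40.0, -60.0, 40.0),
                semi_axes_mm=(35.0, 30.0, 35.0),
                concentrations_mM={"water": hdo, "glc": 0.0},
                linewidth_hz=15.0,
                uptake=(
                    {
                        "glc": (
                            "gamma_variate",
                            {"C0": 0.0, "A": 25.0, "t_p": 10.0, "alpha": 1.5},
                        )
                    }
                ),
            )
        )
    return PhantomSpec(
        matrix=matrix,
        fov=fov,
        compartments=compartments,
        noise_sd=noise_sd,
        seed=seed,
    )
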