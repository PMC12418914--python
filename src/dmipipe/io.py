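"""Serialization: HDF5 stage containers, NIfTI maps, JSON manifests."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import h5py
import nibabel as nib
import numpy as np

from .containers import KSpaceData, SpectralImage
from .params import AcquisitionParams
from .phantom import LabelMap
from .trajectory import Trajectory

__all__ = [
    "save_kspace",
    "load_kspace",
    "save_image",
    "load_image",
    "save_trajectory",
    "load_trajectory",
    "save_nifti",
    "save_label_map",
    "write_manifest",
]


def _write_acq(group: h5py.Group, acq: AcquisitionParams) -> None:
    group.attrs["acq_json"] = json.dumps(acq.to_dict())


def _read_acq(group: h5py.Group) -> AcquisitionParams:
    return AcquisitionParams.from_dict(json.loads(group.attrs["acq_json"]))


def save_kspace(path: str | Path, ksp: KSpaceData) -> None:
    with h5py.File(path, "w") as fh:
        g = fh.create_group("kspace")
        d = g.create_dataset("data", data=ksp.data)
        d.attrs["axes"] = "coil,kz,sample,time"
        g.create_dataset("noise", data=ksp.noise)
        _write_acq(g, ksp.acq)


def load_kspace(path: str | Path) -> KSpaceData:
    with h5py.File(path, "r") as fh:
        g = fh["kspace"]
        return KSpaceData(data=g["data"][()], noise=g["noise"][()], acq=_read_acq(g))


def save_image(path: str | Path, img: SpectralImage) -> None:
    with h5py.File(path, "w") as fh:
        g = fh.create_group("image")
        d = g.create_dataset("data", data=img.data)
        d.attrs["axes"] = ("coil," if img.per_coil else "") + "x,y,z," + (
            "time" if img.domain == "time" else "freq"
        )
        g.attrs["domain"] = img.domain
        g.attrs["per_coil"] = img.per_coil
        if img.freq_axis_hz is not None:
            g.create_dataset("freq_axis_hz", data=img.freq_axis_hz)
        _write_acq(g, img.acq)


def load_image(path: str | Path) -> SpectralImage:
    with h5py.File(path, "r") as fh:
        g = fh["image"]
        freq = g["freq_axis_hz"][()] if "freq_axis_hz" in g else None
        return SpectralImage(
            data=g["data"][()],
            domain=str(g.attrs["domain"]),
            acq=_read_acq(g),
            per_coil=bool(g.attrs["per_coil"]),
            freq_axis_hz=freq,
        )


def save_trajectory(path: str | Path, traj: Trajectory) -> None:
    with h5py.File(path, "w") as fh:
        g = fh.create_group("trajectory")
        for name in ("ring_radii", "ring_counts", "kx", "ky",
                     "ring_index", "kz_offsets", "weights"):
            g.create_dataset(name, data=getattr(traj, name))
        g.attrs["degenerate_cartesian"] = traj.degenerate_cartesian
        g.attrs["k_area"] = traj.k_area


def load_trajectory(path: str | Path) -> Trajectory:
    with h5py.File(path, "r") as fh:
        g = fh["trajectory"]
        return Trajectory(
            ring_radii=g["ring_radii"][()],
            ring_counts=g["ring_counts"][()],
            kx=g["kx"][()],
            ky=g["ky"][()],
            ring_index=g["ring_index"][()],
            kz_offsets=g["kz_offsets"][()],
            weights=g["weights"][()],
            degenerate_cartesian=bool(g.attrs["degenerate_cartesian"]),
            k_area=float(g.attrs.get("k_area", 0.0)),
        )


def _affine(acq: AcquisitionParams) -> np.ndarray:
    aff = np.diag(list(acq.voxel_size_mm) + [1.0])
    for i in range(3):
        aff[i, 3] = -acq.fov[i] / 2.0
    return aff


def save_nifti(path: str | Path, volume: np.ndarray, acq: AcquisitionParams) -> None:
    """Write a (possibly 4D) real-valued map as NIfTI on the phantom grid."""
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float64), _affine(acq))
    nib.save(img, str(path))


def save_label_map(path: str | Path, labels: LabelMap, acq: AcquisitionParams) -> None:
    img = nib.Nifti1Image(labels.labels.astype(np.int16), _affine(acq))
    img.header["descrip"] = json.dumps(
        {str(k): v for k, v in labels.legend.items()}
    )[:79].encode()
    nib.save(img, str(path))


def write_manifest(path: str | Path, manifest: Dict) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_default)
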