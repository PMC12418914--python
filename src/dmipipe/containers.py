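"""In-memory containers passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .params import AcquisitionParams

__all__ = ["KSpaceData", "SpectralImage"]


@dataclass
class KSpaceData:
    """Multi-coil CRT k-space samples plus a noise-only reference block.

    ``data`` is indexed ``(coil, kz_partition, in_plane_sample, fid_time)``;
    in-plane samples are flattened across rings in trajectory order.
    ``noise`` holds noise-only samples ``(coil, sample)`` with the same
    per-channel statistics as the data noise, used to estimate the coil
    noise covariance for whitening.
    """

    data: np.ndarray              # complex (n_coils, n_kz, n_samples, n_t)
    noise: np.ndarray             # complex (n_coils, n_noise)
    acq: AcquisitionParams

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    @property
    def n_kz(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_t(self) -> int:
        return self.data.shape[3]


@dataclass
class SpectralImage:
    """Spatial-spectral image: complex voxel grid x FID-time (or frequency).

    ``data`` has shape ``(nx, ny, nz, n)`` or ``(n_coils, nx, ny, nz, n)``
    when ``per_coil`` is True. ``domain`` is ``"time"`` (FID) or ``"freq"``
    (spectrum). In the frequency domain ``freq_axis_hz`` gives the offset
    from the carrier and ``ppm_axis`` the chemical-shift axis anchored at
    ``acq.reference_ppm``.
    """

    data: np.ndarray
    domain: str                   # "time" | "freq"
    acq: AcquisitionParams
    per_coil: bool = False
    freq_axis_hz: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.domain not in ("time", "freq"):
            raise ValueError("domain must be 'time' or 'freq'")
        expected_ndim = 5 if self.per_coil else 4
        if self.data.ndim != expected_ndim:
            raise ValueError(
                f"data must have {expected_ndim} axes for per_coil={self.per_coil}"
            )
        if self.domain == "freq":
            if self.freq_axis_hz is None:
                raise ValueError("frequency-domain image requires freq_axis_hz")
            if self.freq_axis_hz.size != self.data.shape[-1]:
                raise ValueError("freq_axis_hz length mismatch")

    @property
    def dwell_s(self) -> float:
        return self.acq.dwell_s

    @property
    def voxel_size_mm(self):
        return self.acq.voxel_size_mm

    @property
    def ppm_axis(self) -> np.ndarray:
        """Chemical-shift axis (ppm), strictly increasing with frequency."""
        if self.freq_axis_hz is None:
            raise ValueError("ppm axis only defined in the frequency domain")
        return np.asarray(self.acq.hz_to_ppm(self.freq_axis_hz))

    @property
    def grid_shape(self):
        return self.data.shape[-4:-1]

    def copy_with(self, data: np.ndarray, **kw) -> "SpectralImage":
        out = SpectralImage(
            data=data,
            domain=kw.get("domain", self.domain),
            acq=self.acq,
            per_coil=kw.get("per_coil", self.per_coil),
            freq_axis_hz=kw.get("freq_axis_hz", self.freq_axis_hz),
        )
        return out
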