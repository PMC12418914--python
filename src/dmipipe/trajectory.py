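"""Density-weighted concentric-ring k-space trajectories.

In-plane k-space is covered by ``n_rings`` concentric circles of increasing
radius; the through-plane direction uses ordinary Cartesian phase encoding
(one partition per kz step). Each ring is assumed to deliver the full FID
(96 points at 380 Hz bandwidth by default); temporal interleaving used on
hardware to reach that bandwidth is abstracted away.

A degenerate Cartesian mode returns exactly the integer grid points of the
target matrix, which makes the adjoint non-uniform DFT coincide with the
inverse FFT and serves as the reconstruction oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from .params import AcquisitionParams

__all__ = ["Trajectory", "make_crt_trajectory", "density_weights"]


@dataclass
class Trajectory:
    """Concentric-ring (or degenerate Cartesian) k-space sampling scheme.

    ``kx``/``ky`` hold all in-plane sample coordinates in 1/mm, flattened
    across rings; ``ring_index`` maps each sample to its ring. ``kz_offsets``
    lists the Cartesian phase-encode steps in 1/mm. ``weights`` are the
    per-sample density-compensation weights, normalized to sum to 1.
    """

    ring_radii: np.ndarray          # (n_rings,) 1/mm
    ring_counts: np.ndarray         # (n_rings,) angular samples per ring
    kx: np.ndarray                  # (n_samples,) 1/mm
    ky: np.ndarray                  # (n_samples,) 1/mm
    ring_index: np.ndarray          # (n_samples,) int
    kz_offsets: np.ndarray          # (n_kz,) 1/mm
    weights: np.ndarray             # (n_samples,) sums to 1
    degenerate_cartesian: bool = False
    #: total in-plane k-space area covered by the sampling (1/mm^2); used by
    #: the adjoint as the quadrature scale so extended objects keep their
    #: amplitude (a disk covers pi/4 of the Cartesian square's area)
    k_area: float = 0.0

    @property
    def n_samples(self) -> int:
        return int(self.kx.size)

    @property
    def n_kz(self) -> int:
        return int(self.kz_offsets.size)

    def validate(self, acq: AcquisitionParams) -> None:
        """Raise if the trajectory cannot support the target matrix/FOV."""
        kmax_x = acq.matrix[0] / (2.0 * acq.fov[0])
        if self.kx.size == 0:
            raise ValueError("empty trajectory")
        if np.hypot(self.kx, self.ky).max() > kmax_x * (1 + 1e-9):
            raise ValueError("trajectory radius exceeds matrix Nyquist extent")
        if np.any(self.weights <= 0):
            raise ValueError("density weights must be strictly positive")


def _ring_radii(k_max: float, n_rings: int) -> np.ndarray:
    # Half-offset scheme: no ring at k=0, outermost ring exactly at k_max.
    i = np.arange(n_rings)
    return k_max * (i + 0.5) / (n_rings - 0.5)


def make_crt_trajectory(
    acq: AcquisitionParams,
    n_rings: int | None = None,
    window: str = "uniform",
    degenerate_cartesian: bool = False,
) -> Trajectory:
    """Build the concentric-ring trajectory for an acquisition.

    Parameters
    ----------
    acq : AcquisitionParams
        Supplies matrix, FOV and (default) ring count.
    n_rings : int, optional
        Number of rings; defaults to ``acq.n_rings``.
    window : {"uniform", "hamming"}
        Radial density window passed to :func:`density_weights`.
    degenerate_cartesian : bool
        If True, return exactly the Cartesian grid points of the target
        matrix with uniform weights (oracle hook for the adjoint NUDFT).

    Notes
    -----
    Ring radii follow ``r_i = k_max * (i + 1/2) / (n_rings - 1/2)`` with
    ``k_max = matrix/(2*FOV)`` so the outermost ring reaches the matrix
    Nyquist radius; each ring carries at least the angular Nyquist count
    ``ceil(2*pi*r_i/dk)``. kz uses ``matrix_z`` equally spaced phase encodes.
    """
    nx, ny, nz = acq.matrix
    fx, fy, fz = acq.fov
    dk = 1.0 / fx  # in-plane k-space pitch (FOV assumed square in-plane)

    kz_offsets = (np.arange(nz) - nz // 2) / fz

    if degenerate_cartesian:
        mx = np.arange(nx) - nx // 2
        my = np.arange(ny) - ny // 2
        gx, gy = np.meshgrid(mx / fx, my / fy, indexing="ij")
        kx = gx.ravel()
        ky = gy.ravel()
        n = kx.size
        traj = Trajectory(
            ring_radii=np.hypot(kx, ky),
            ring_counts=np.ones(n, dtype=int),
            kx=kx,
            ky=ky,
            ring_index=np.arange(n),
            kz_offsets=kz_offsets,
            weights=np.full(n, 1.0 / n),
            degenerate_cartesian=True,
            k_area=nx * ny / (fx * fy),
        )
        return traj

    if n_rings is None:
        n_rings = acq.n_rings
    if n_rings < 1:
        raise ValueError("n_rings must be >= 1")
    k_max = nx / (2.0 * fx)
    # Need enough rings that the radial pitch supports the matrix FOV
    # (ring spacing <= 1/FOV, i.e. n_rings - 1/2 >= nx/2).
    if n_rings < int(np.ceil((nx + 1) / 2)):
        raise ValueError(
            f"n_rings={n_rings} too few to support matrix {nx} "
            f"(need >= {int(np.ceil((nx + 1) / 2))})"
        )

    radii = _ring_radii(k_max, n_rings)
    counts = np.maximum(np.ceil(2.0 * np.pi * radii / dk).astype(int), 4)

    kx_parts, ky_parts, idx_parts = [], [], []
    for i, (r, c) in enumerate(zip(radii, counts)):
        theta = 2.0 * np.pi * np.arange(c) / c
        kx_parts.append(r * np.cos(theta))
        ky_parts.append(r * np.sin(theta))
        idx_parts.append(np.full(c, i, dtype=int))

    traj = Trajectory(
        ring_radii=radii,
        ring_counts=counts,
        kx=np.concatenate(kx_parts),
        ky=np.concatenate(ky_parts),
        ring_index=np.concatenate(idx_parts),
        kz_offsets=kz_offsets,
        weights=np.empty(0),
        degenerate_cartesian=False,
    )
    pitch = radii[1] - radii[0] if n_rings > 1 else radii[0]
    traj.k_area = float(np.pi * (radii[-1] + 0.5 * pitch) ** 2)
    traj.weights = density_weights(traj, window)
    return traj


def density_weights(traj: Trajectory, window: str = "uniform") -> np.ndarray:
    """Per-sample density-compensation weights for a ring trajectory.

    The weight of a sample on ring ``i`` is proportional to the annulus area
    represented by that ring divided by its angular sample count, optionally
    multiplied by a radial window; the result is normalized to sum to 1.
    For equally spaced rings the annulus area is proportional to the ring
    radius, so a uniform window yields radius-proportional ring weights.
    """
    if traj.degenerate_cartesian:
        w = np.full(traj.n_samples, 1.0 / traj.n_samples)
        return w

    radii = traj.ring_radii
    n_rings = radii.size
    # Annulus edges midway between rings; innermost annulus starts at 0,
    # outermost ends half a pitch beyond the last ring.
    edges = np.empty(n_rings + 1)
    edges[1:-1] = 0.5 * (radii[:-1] + radii[1:])
    edges[0] = 0.0
    pitch = radii[1] - radii[0] if n_rings > 1 else radii[0]
    edges[-1] = radii[-1] + 0.5 * pitch
    annulus_area = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)

    if window == "uniform":
        win = np.ones(n_rings)
    elif window == "hamming":
        k_max = radii[-1]
        win = 0.54 + 0.46 * np.cos(np.pi * radii / k_max)
    else:
        raise ValueError(f"unknown window {window!r}")

    per_ring = annulus_area * win / traj.ring_counts
    w = per_ring[traj.ring_index]
    return w / w.sum()


def plot_rings(traj: Trajectory, path: str) -> None:
    """Write an SVG of the ring layout (documentation helper)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    sc = ax.scatter(traj.kx, traj.ky, c=traj.weights, s=4, cmap="viridis")
    ax.set_aspect("equal")
    ax.set_xlabel("kx (1/mm)")
    ax.set_ylabel("ky (1/mm)")
    ax.set_title(f"{traj.ring_radii.size} rings, {traj.n_samples} samples")
    fig.colorbar(sc, ax=ax, label="density weight")
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)
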