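"""Whitened-SVD (WSVD) multi-coil combination.

Per voxel, the coil x time FID matrix is whitened with the inverse Cholesky
factor of the coil noise covariance and reduced to its dominant rank-1
component; the combined FID is the leading right-singular vector scaled by
its singular value, with the global phase fixed so the first FID point is
real and non-negative (stable real-part fitting downstream).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .containers import SpectralImage

__all__ = ["NoiseCovariance", "estimate_noise_cov", "wsvd_combine", "combine_image"]


@dataclass
class NoiseCovariance:
    """Hermitian coil x coil complex noise covariance."""

    matrix: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(m, m.conj().T):
            raise ValueError("covariance must be Hermitian")

    @property
    def n_coils(self) -> int:
        return self.matrix.shape[0]

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    @property
    def rank_deficient(self) -> bool:
        return self.condition_number > 1e6


def estimate_noise_cov(noise_block: np.ndarray) -> NoiseCovariance:
    """Sample covariance across channels from a noise-only block.

    ``noise_block`` has shape (n_coils, n_samples); requires at least
    10 x n_coils samples. The result is explicitly Hermitian-symmetrized.
    """
    noise = np.asarray(noise_block)
    if noise.ndim != 2:
        raise ValueError("noise block must be (n_coils, n_samples)")
    n_coils, n = noise.shape
    if n < 10 * n_coils:
        raise ValueError(f"need >= {10 * n_coils} noise samples, got {n}")
    centered = noise - noise.mean(axis=1, keepdims=True)
    cov = centered @ centered.conj().T / (n - 1)
    cov = 0.5 * (cov + cov.conj().T)
    return NoiseCovariance(matrix=cov, n_samples=n)


def _whitener(cov: NoiseCovariance) -> np.ndarray:
    """Inverse Cholesky factor, ridge-regularized if near-singular."""
    m = cov.matrix.copy()
    if cov.rank_deficient:
        m = m + 1e-6 * (np.trace(m).real / m.shape[0]) * np.eye(m.shape[0])
    L = np.linalg.cholesky(m)
    return np.linalg.inv(L)


def wsvd_combine(
    voxel_matrix: np.ndarray, cov: NoiseCovariance
) -> Tuple[np.ndarray, np.ndarray]:
    """Combine one voxel's coil x time FID matrix.

    Returns ``(combined_fid, coil_weights)`` where ``coil_weights`` is the
    leading left-singular vector expressed in whitened coil space. All-zero
    input returns zeros with a warning.
    """
    X = np.asarray(voxel_matrix)
    if X.ndim != 2 or X.shape[0] != cov.n_coils:
        raise ValueError("voxel matrix must be (n_coils, n_time)")
    if not np.any(X):
        warnings.warn("all-zero voxel passed to WSVD; returning zeros")
        return np.zeros(X.shape[1], dtype=complex), np.zeros(X.shape[0], dtype=complex)

    W = _whitener(cov)
    Xw = W @ X
    U, s, Vh = np.linalg.svd(Xw, full_matrices=False)
    combined = s[0] * Vh[0]
    weights = U[:, 0]
    # zero-phase convention at the first FID point
    if combined[0] != 0:
        phase = combined[0] / abs(combined[0])
        combined = combined * phase.conj()
        weights = weights * phase
    return combined, weights


def combine_image(img: SpectralImage, cov: NoiseCovariance) -> SpectralImage:
    """Apply WSVD voxel-by-voxel to a per-coil FID-domain image."""
    if not img.per_coil:
        raise ValueError("image is already coil-combined")
    n_coils = img.data.shape[0]
    if n_coils != cov.n_coils:
        raise ValueError("coil count mismatch with covariance")
    nx, ny, nz, nt = img.data.shape[1:]

    W = _whitener(cov)
    flat = img.data.reshape(n_coils, nx * ny * nz, nt)
    out = np.zeros((nx * ny * nz, nt), dtype=complex)
    for v in range(flat.shape[1]):
        X = flat[:, v, :]
        if not np.any(X):
            continue
        Xw = W @ X
        U, s, Vh = np.linalg.svd(Xw, full_matrices=False)
        combined = s[0] * Vh[0]
        if combined[0] != 0:
            combined = combined * (combined[0] / abs(combined[0])).conj()
        out[v] = combined
    return img.copy_with(out.reshape(nx, ny, nz, nt), per_coil=False)
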