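"""Concentration estimation, relaxation corrections, B1+ mapping, exclusions.

Metabolite maps are converted to mM by internal referencing to the
natural-abundance HDO signal of a pre-tracer reference scan of the same
voxel, with steady-state (Ernst) saturation and acquisition-delay T2 decay
corrections and the deuteron count per molecule taken into account.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .params import AcquisitionParams, RelaxationAssumptions

__all__ = [
    "FlipAngleMap",
    "ConcentrationMap",
    "double_angle_b1",
    "saturation_factor",
    "ernst_angle_deg",
    "t2_correction",
    "estimate_concentration",
    "apply_exclusions",
    "mM_to_mg_per_dl",
]

GLUCOSE_MOLAR_MASS = 180.16  # g/mol


@dataclass
class FlipAngleMap:
    """Per-voxel flip angle (degrees) from double-angle B1+ mapping."""

    degrees: np.ndarray
    valid: np.ndarray

    def mean_valid(self) -> float:
        return float(self.degrees[self.valid].mean())


@dataclass
class ConcentrationMap:
    """Voxel-wise metabolite concentration with exclusion flags.

    ``values_mM`` may carry trailing time axes; flags are per voxel per time
    point and are recorded independently (a voxel can carry several flags).
    """

    values_mM: np.ndarray
    metabolite: str
    crlb_excluded: np.ndarray = None
    conc_excluded: np.ndarray = None
    unfit: np.ndarray = None

    def __post_init__(self) -> None:
        shape = self.values_mM.shape
        for name in ("crlb_excluded", "conc_excluded", "unfit"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(shape, dtype=bool))

    @property
    def included(self) -> np.ndarray:
        return ~(self.crlb_excluded | self.conc_excluded | self.unfit)


def double_angle_b1(img_alpha: np.ndarray, img_2alpha: np.ndarray) -> FlipAngleMap:
    """Flip-angle map from magnitude images at nominal alpha and 2*alpha.

    With long TR, S_alpha ~ sin(alpha) and S_2alpha ~ sin(2 alpha), so
    ``alpha = arccos(S_2alpha / (2 S_alpha))``. Voxels where the ratio falls
    outside (0, 2) or the denominator vanishes are marked invalid.
    """
    img_alpha = np.asarray(img_alpha, dtype=float)
    img_2alpha = np.asarray(img_2alpha, dtype=float)
    if img_alpha.shape != img_2alpha.shape:
        raise ValueError("image shapes differ")
    degrees = np.zeros_like(img_alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = img_2alpha / img_alpha  # in (0, 2) for a valid voxel
    valid = (img_alpha > 0) & np.isfinite(ratio) & (ratio > 0) & (ratio < 2)
    degrees[valid] = np.degrees(np.arccos(0.5 * ratio[valid]))
    return FlipAngleMap(degrees=degrees, valid=valid)


def saturation_factor(TR_ms: float, T1_ms: float, flip_deg: float) -> float:
    """Steady-state saturation factor of a spoiled FID acquisition.

    ``f = sin(a) (1 - E1) / (1 - E1 cos(a))`` with ``E1 = exp(-TR/T1)``;
    the Ernst formula for the signal fraction relative to full relaxation.
    """
    if TR_ms <= 0 or T1_ms <= 0:
        raise ValueError("TR and T1 must be positive")
    e1 = np.exp(-TR_ms / T1_ms)
    a = np.radians(flip_deg)
    return float(np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a)))


def ernst_angle_deg(TR_ms: float, T1_ms: float) -> float:
    """Flip angle maximizing the steady-state signal: arccos(exp(-TR/T1))."""
    return float(np.degrees(np.arccos(np.exp(-TR_ms / T1_ms))))


def t2_correction(delay_ms: float, T2_ms: float) -> float:
    """Signal fraction surviving the acquisition delay: exp(-delay/T2)."""
    if T2_ms <= 0:
        raise ValueError("T2 must be positive")
    return float(np.exp(-delay_ms / T2_ms))


def estimate_concentration(
    amplitude: np.ndarray | float,
    water_ref_amplitude: np.ndarray | float,
    relax: RelaxationAssumptions,
    acq: AcquisitionParams,
    metabolite: str = "glc",
    apply_saturation: bool = True,
    apply_t2: bool = True,
) -> np.ndarray | float:
    """Metabolite concentration in mM by internal water referencing.

    ``C = (A_met / A_water_ref) * (f_sat,w f_T2,w)/(f_sat,m f_T2,m)
    * (n_w / n_m) * C_HDO,natural``. Correction factors can be switched off
    individually so each can be verified in isolation. Non-positive
    reference amplitudes yield NaN (voxel unfit).
    """
    amplitude = np.asarray(amplitude, dtype=float)
    ref = np.asarray(water_ref_amplitude, dtype=float)

    factor = relax.natural_hdo_mM * (
        relax.n_labels_water / relax.n_labels_of(metabolite)
    )
    if apply_saturation:
        factor *= saturation_factor(
            acq.TR, relax.T1_water, acq.flip_angle
        ) / saturation_factor(acq.TR, relax.t1_of(metabolite), acq.flip_angle)
    if apply_t2:
        factor *= t2_correction(
            acq.acquisition_delay, relax.T2_water
        ) / t2_correction(acq.acquisition_delay, relax.t2_of(metabolite))

    with np.errstate(divide="ignore", invalid="ignore"):
        conc = np.where(ref > 0, amplitude / ref * factor, np.nan)
    if conc.ndim == 0:
        return float(conc)
    return conc


def apply_exclusions(
    conc: ConcentrationMap,
    crlb_percent: np.ndarray,
    mask: Optional[np.ndarray] = None,
    crlb_threshold: float = 50.0,
    conc_threshold_mM: Optional[float] = 5.0,
) -> Tuple[ConcentrationMap, Dict[str, float]]:
    """Flag voxels failing the fit-quality and plausibility filters.

    Voxels with amplitude CRLB strictly greater than ``crlb_threshold``
    percent, and (for glucose) voxels with concentration strictly greater
    than ``conc_threshold_mM`` (the 5 mM / 90 mg/dL stomach-contamination
    guard), are flagged. Ties at the threshold are retained. Returns the
    flagged map and integer counts plus the surviving-voxel percentage over
    ``mask`` (whole grid if None).
    """
    values = conc.values_mM
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    mask = np.broadcast_to(mask, values.shape)

    crlb_excluded = conc.crlb_excluded | (
        mask & (np.asarray(crlb_percent) > crlb_threshold)
    )
    unfit = conc.unfit | (mask & ~np.isfinite(values))
    if conc_threshold_mM is not None:
        conc_excluded = conc.conc_excluded | (
            mask & np.isfinite(values) & (values > conc_threshold_mM)
        )
    else:
        conc_excluded = conc.conc_excluded

    out = ConcentrationMap(
        values_mM=values,
        metabolite=conc.metabolite,
        crlb_excluded=crlb_excluded,
        conc_excluded=conc_excluded,
        unfit=unfit,
    )
    n_mask = int(mask.sum())
    excluded = mask & (crlb_excluded | conc_excluded | unfit)
    counts = {
        "n_mask": n_mask,
        "n_crlb_excluded": int((mask & crlb_excluded).sum()),
        "n_conc_excluded": int((mask & conc_excluded).sum()),
        "n_unfit": int((mask & unfit).sum()),
        "n_excluded": int(excluded.sum()),
        "percent_excluded": 100.0 * excluded.sum() / n_mask if n_mask else 0.0,
        "percent_surviving": 100.0 * (n_mask - excluded.sum()) / n_mask
        if n_mask
        else 0.0,
    }
    return out, counts


def mM_to_mg_per_dl(c_mM: float | np.ndarray, molar_mass: float = GLUCOSE_MOLAR_MASS):
    """Convert a concentration in mM to mg/dL (c * M / 10)."""
    c = np.asarray(c_mM, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    out = c * molar_mass / 10.0
    return float(out) if out.ndim == 0 else out
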