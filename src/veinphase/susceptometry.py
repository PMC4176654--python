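"""Intravascular susceptometry: phase -> field -> susceptibility -> Y_v.

The phase shift between a vein and adjacent tissue measures the
vein-tissue field shift ``dB = dphi / (gamma * TE)``, which relates to the
vein-tissue susceptibility difference through a geometry-dependent scaling
factor ``A``:  ``dB = A * B0 * dchi_iv``.  With the deoxy-oxy haemoglobin
susceptibility difference ``dchi_do`` and haematocrit ``Hct``,

    dchi_iv = Hct * (1 - Yv) * dchi_do

so the venous oxygen saturation follows as

    Yv = 1 - dphi_iv / (A * gamma * TE * B0 * Hct * dchi_do).

For an infinite cylinder tilted at angle ``theta`` to B0 the scaling
factor is ``A = (3*cos^2(theta) - 1) / 6`` (Method I); Method II computes
``A`` from a forward field calculation of the actual vessel shape (see
:mod:`veinphase.forward`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .params import AcquisitionParams, BloodGasParams

#: |phase| above this (rad) inside an ROI triggers a wrap warning.
WRAP_GUARD = math.pi - 0.05


class MagicAngleError(ValueError):
    """Raised when the scaling factor is zero: at the magic angle the
    intravascular phase carries no susceptibility information."""


@dataclass
class YvResult:
    """A venous-oxygenation estimate with its provenance.

    ``ancillary`` carries the scaling factor A (Methods I/II) or the
    fitted hyperoxia/normoxia slope a (Method III).
    """

    yv: float
    method: str
    uncertainty: float = 0.0
    ancillary: float = float("nan")
    flags: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in {"I", "II", "III"}:
            raise ValueError(f"unknown method tag {self.method!r}")
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be >= 0")

    def summary(self) -> str:
        lines = [
            "Venous oxygenation estimate",
            "=" * 42,
            f"method                 : {self.method}",
            f"Yv                     : {self.yv:.4f}",
            f"standard error         : {self.uncertainty:.4f}",
        ]
        name = "scaling factor A" if self.method in ("I", "II") else "fitted slope a"
        lines.append(f"{name:<23}: {self.ancillary:.4f}")
        for k, v in self.flags.items():
            lines.append(f"flag {k:<18}: {v}")
        return "\n".join(lines)


def phase_to_field(dphi, acq: AcquisitionParams):
    """Convert a phase shift (rad) to a field shift (tesla):
    ``dB = dphi / (gamma * TE)``."""
    return np.asarray(dphi, dtype=float) / (acq.gamma * acq.te)


def infinite_cylinder_scaling(theta):
    """Scaling factor of an infinite cylinder at tilt ``theta`` (rad) to B0:
    ``A = (3*cos^2(theta) - 1) / 6``; range [-1/6, 1/3]."""
    c = np.cos(theta)
    return (3.0 * c * c - 1.0) / 6.0


def susceptibility_to_yv(
    dchi_iv,
    blood: BloodGasParams,
    tissue_correction: bool = False,
    correction_form: str = "additive",
):
    """Invert ``dchi_iv = Hct * (1 - Yv) * dchi_do`` for Y_v.

    With ``tissue_correction`` the assumption that tissue shares the
    susceptibility of fully oxygenated haemoglobin is dropped.  The default
    ``"additive"`` form adds ``dchi_oxy / dchi_do`` to Y_v (a small-term
    approximation, valid for Yv near 1 in the correction term); the
    ``"exact"`` form inverts the corrected relation
    ``dchi_iv = Hct*(1-Yv)*dchi_do + Hct*Yv*dchi_oxy`` exactly.

    Values outside [0, 1] are returned unchanged but trigger a warning:
    they signal noise, a wrapped phase, or a sign-convention mismatch.
    """
    dchi_iv = np.asarray(dchi_iv, dtype=float)
    base = 1.0 - dchi_iv / (blood.hct * blood.dchi_do)
    if not tissue_correction:
        yv = base
    elif correction_form == "additive":
        yv = base + blood.dchi_oxy / blood.dchi_do
    elif correction_form == "exact":
        yv = (1.0 - dchi_iv / (blood.hct * blood.dchi_do)) / (
            1.0 - blood.dchi_oxy / blood.dchi_do
        )
    else:
        raise ValueError(f"unknown correction_form {correction_form!r}")
    if np.any(yv < 0) or np.any(yv > 1):
        warnings.warn(
            "Yv outside [0, 1]: physically implausible (noise, wrap, or "
            "phase sign convention)",
            stacklevel=2,
        )
    return yv if yv.ndim else float(yv)


def yv_from_phase(
    dphi_iv: float,
    A: float,
    acq: AcquisitionParams,
    blood: BloodGasParams,
    method: str = "I",
    se_dphi: float = 0.0,
    tissue_correction: bool = False,
    correction_form: str = "additive",
    phase_sign: int = 1,
) -> YvResult:
    """Estimate Y_v from the intravascular phase shift.

    Composes the phase-to-field conversion, the geometric scaling and the
    susceptibility relation.  ``phase_sign`` = -1 flips the convention for
    scanners where a paramagnetic parallel vein yields negative phase.

    Raises
    ------
    MagicAngleError
        If ``A == 0`` (vessel at the magic angle).
    """
    if abs(A) < 1e-12:
        raise MagicAngleError(
            "scaling factor A = 0 (magic angle): intravascular phase carries "
            "no susceptibility information"
        )
    denom = A * acq.gamma * acq.te * acq.b0 * blood.hct * blood.dchi_do
    dchi_iv = phase_sign * dphi_iv / (A * acq.gamma * acq.te * acq.b0)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        yv = susceptibility_to_yv(
            dchi_iv, blood, tissue_correction=tissue_correction,
            correction_form=correction_form,
        )
    flags = {}
    if caught:
        flags["yv_out_of_range"] = True
        warnings.warn(str(caught[0].message), stacklevel=2)
    se = abs(se_dphi / denom)
    return YvResult(yv=float(yv), method=method, uncertainty=se, ancillary=A, flags=flags)


def delta_phi_iv(phase: np.ndarray, iv_roi: np.ndarray, ref_roi: np.ndarray):
    """Mean filtered phase over the intravascular ROI minus the reference
    ROI, with a standard error from the two ROI SEMs in quadrature.

    Returns
    -------
    (dphi, se) : tuple of float
    """
    phase = np.asarray(phase, dtype=float)
    iv_roi = np.asarray(iv_roi, dtype=bool)
    ref_roi = np.asarray(ref_roi, dtype=bool)
    if iv_roi.shape != phase.shape or ref_roi.shape != phase.shape:
        raise ValueError("ROI shapes must match the phase volume")
    if not iv_roi.any():
        raise ValueError("intravascular ROI is empty")
    if not ref_roi.any():
        raise ValueError("reference ROI is empty")
    if np.any(iv_roi & ref_roi):
        raise ValueError("intravascular and reference ROIs overlap")
    iv_vals = phase[iv_roi]
    ref_vals = phase[ref_roi]
    if np.max(np.abs(iv_vals)) > WRAP_GUARD:
        warnings.warn(
            "phase near +/-pi inside the intravascular ROI: possible wrap; "
            "Yv estimate may be invalid",
            stacklevel=2,
        )

    def _sem(v):
        return float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0

    dphi = float(iv_vals.mean() - ref_vals.mean())
    se = math.hypot(_sem(iv_vals), _sem(ref_vals))
    return dphi, se
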