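"""Parameter containers: acquisition geometry and blood-gas physiology."""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np

from . import constants


@dataclass(frozen=True)
class AcquisitionParams:
    """Gradient-echo acquisition parameters.

    Parameters
    ----------
    te : float
        Echo time in seconds.
    b0 : float
        Static field strength in tesla.
    gamma : float
        Proton gyromagnetic ratio in rad s^-1 T^-1.
    field_direction : tuple of float
        Unit vector of B0 in image (voxel) coordinates.  The caller is
        responsible for composing scanner angles with any registration
        transform before passing the vector.
    """

    te: float
    b0: float
    gamma: float = constants.GAMMA_PROTON
    field_direction: tuple = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if self.te <= 0:
            raise ValueError(f"te must be positive, got {self.te}")
        if self.b0 <= 0:
            raise ValueError(f"b0 must be positive, got {self.b0}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        n = np.asarray(self.field_direction, dtype=float)
        if n.shape != (3,):
            raise ValueError("field_direction must be a 3-vector")
        if abs(float(np.linalg.norm(n)) - 1.0) > 1e-9:
            raise ValueError("field_direction must be a unit vector (|v|=1 within 1e-9)")

    @property
    def direction(self) -> np.ndarray:
        return np.asarray(self.field_direction, dtype=float)

    def replace(self, **kw) -> "AcquisitionParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class BloodGasParams:
    """Blood and gas-challenge physiology.

    ``dchi_do`` is the volume susceptibility difference between fully
    deoxygenated and fully oxygenated haemoglobin (SI), ``dchi_oxy`` the
    difference between fully oxygenated haemoglobin and tissue (SI; only
    used when the tissue-susceptibility correction is enabled).
    ``pao2_no`` / ``pao2_ho`` are arterial PO2 at normoxia / hyperoxia in
    mmHg; end-tidal PO2 is taken as a direct proxy for arterial PO2.
    """

    hct: float = constants.HCT_DEFAULT
    dchi_do: float = constants.DCHI_DO_SI
    dchi_oxy: float = constants.DCHI_OXY_SI
    psi: float = constants.PSI_O2
    hb: float = constants.HB_DEFAULT
    epsilon: float = constants.EPSILON_O2
    pao2_no: float = 110.0
    pao2_ho: float = 500.0

    def __post_init__(self):
        if not 0.0 < self.hct < 1.0:
            raise ValueError(f"hct must lie in (0, 1), got {self.hct}")
        if self.dchi_do <= 0:
            raise ValueError("dchi_do must be positive")
        for name in ("psi", "hb", "epsilon", "pao2_no", "pao2_ho"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def replace(self, **kw) -> "BloodGasParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)
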