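"""Gas-exchange model: end-tidal O2 -> hyperoxia-induced change in Y_v.

At normoxia arterial haemoglobin is nearly saturated, so the extra O2
carried at hyperoxia is mostly dissolved in plasma.  Assuming the amount
of O2 extracted by tissue is unchanged between gas states, the venous
saturation rises by

    dYh = dSaO2 + epsilon * dPaO2 / (psi * [Hb])

where SaO2(PaO2) follows the Severinghaus dissociation curve

    SaO2 = ( 23400 / (PaO2^3 + 150 * PaO2) + 1 )^-1

and arterial PO2 is approximated by the measured end-tidal PO2.
"""

from __future__ import annotations

import numpy as np

from .params import BloodGasParams


def severinghaus_sao2(pao2):
    """Arterial O2 saturation (fraction) from PaO2 (mmHg), Severinghaus
    dissociation curve.  Strictly increasing, -> 1 as PaO2 -> infinity."""
    pao2 = np.asarray(pao2, dtype=float)
    if np.any(pao2 <= 0):
        raise ValueError("pao2 must be positive")
    sao2 = 1.0 / (23400.0 / (pao2 ** 3 + 150.0 * pao2) + 1.0)
    return sao2 if sao2.ndim else float(sao2)


def delta_yh(blood: BloodGasParams) -> float:
    """Hyperoxia-induced increase in venous oxygenation (fraction).

    Uses ``blood.pao2_no`` and ``blood.pao2_ho`` (end-tidal PO2 as a
    proxy for arterial PO2) and the carrying-capacity/solubility
    constants psi, [Hb], epsilon.
    """
    if blood.pao2_ho < blood.pao2_no:
        raise ValueError("pao2_ho must be >= pao2_no for a hyperoxia challenge")
    dsao2 = severinghaus_sao2(blood.pao2_ho) - severinghaus_sao2(blood.pao2_no)
    dpao2 = blood.pao2_ho - blood.pao2_no
    return float(dsao2 + blood.epsilon * dpao2 / (blood.psi * blood.hb))
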