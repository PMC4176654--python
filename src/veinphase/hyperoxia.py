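"""Hyperoxia phase contrast (Method III): per-vein Y_v from paired
normoxia/hyperoxia phase volumes.

The phase distribution in and around a vein at normoxia, dominated by
intravascular deoxyhaemoglobin, serves as a spatial template for the
phase change on hyperoxia.  Fitting the hyperoxia phase onto the
normoxia phase,

    phi_HO(r) = a * phi_NO(r) + k,

with errors on both coordinates (York regression), the slope measures the
ratio of vein-tissue susceptibility differences a = dchi_HO / dchi_NO.
With dchi = Hct * (1 - Yv) * dchi_do at normoxia and
Hct * (1 - Yv - dYh) * dchi_do at hyperoxia this inverts to

    Yv = 1 - dYh / (1 - a),

independent of the vein's shape, size and orientation, and of any
constant phase offset between the two gas states (absorbed by k).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .params import BloodGasParams
from .york import york_fit

logger = logging.getLogger(__name__)


def yv_from_slope(
    a: float,
    dyh: float,
    blood: BloodGasParams | None = None,
    tissue_correction: bool = False,
):
    """Invert the hyperoxia/normoxia susceptibility ratio for Y_v:
    ``Yv = 1 - dYh / (1 - a)``, optionally with the additive
    tissue-susceptibility correction ``+ dchi_oxy / dchi_do``."""
    yv = 1.0 - dyh / (1.0 - a)
    if tissue_correction:
        if blood is None:
            raise ValueError("blood params required for tissue correction")
        yv = yv + blood.dchi_oxy / blood.dchi_do
    return yv


def slope_from_yv(yv: float, dyh: float) -> float:
    """Forward relation: ``a = dchi_HO/dchi_NO = 1 - dYh/(1 - Yv)``."""
    return 1.0 - dyh / (1.0 - yv)


def fit_veins(
    phase_no: np.ndarray,
    phase_ho: np.ndarray,
    veins,
    snr: float,
    dyh: float,
    blood: BloodGasParams | None = None,
    min_points: int = 10,
    tissue_correction: bool = False,
) -> pd.DataFrame:
    """York-fit each vein's hyperoxia phase onto its normoxia phase.

    Per-voxel phase errors are sigma_phi = 1/SNR on both axes (first-order
    phase noise at magnitude SNR >> 1).  Veins whose fitted slope is >= 1
    are flagged invalid (a non-physical susceptibility increase on
    hyperoxia); veins with fewer than ``min_points`` voxels are skipped.

    Returns a DataFrame with columns
    label, n_voxels, a, se_a, k, yv, se_yv, valid, converged.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    sigma = 1.0 / snr
    rows = []
    for i, roi in enumerate(veins.rois):
        label = i + 1
        n = int(roi.sum())
        if n < min_points:
            logger.info("vein %d skipped: %d voxels < min_points=%d", label, n, min_points)
            continue
        x = phase_no[roi]
        y = phase_ho[roi]
        if np.ptp(x) == 0:
            logger.info("vein %d skipped: zero phase variance", label)
            continue
        fit = york_fit(x, y, sigma, sigma)
        a = fit.slope_a
        valid = a < 1.0
        if valid:
            yv = yv_from_slope(a, dyh, blood, tissue_correction)
            # d(Yv)/da = -dYh/(1-a)^2
            se_yv = abs(dyh / (1.0 - a) ** 2) * fit.se_slope
        else:
            yv = np.nan
            se_yv = np.nan
        rows.append(
            dict(
                label=label,
                n_voxels=n,
                a=a,
                se_a=fit.se_slope,
                k=fit.intercept_k,
                yv=yv,
                se_yv=se_yv,
                valid=valid,
                converged=fit.converged,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label", "n_voxels", "a", "se_a", "k", "yv", "se_yv",
            "valid", "converged",
        ],
    )


def weighted_mode(
    values,
    weights=None,
    bin_width: float = 0.02,
    vrange: tuple = (0.0, 1.0),
) -> float:
    """Mode of a (weighted) histogram: centre of the maximal bin.

    The default bin width of 0.02 on [0, 1] resolves the distribution of
    per-vein Y_v without empty-bin noise at realistic vein counts; each
    vein is typically weighted by its voxel count.
    """
    values = np.asarray(values, dtype=float)
    good = np.isfinite(values)
    values = values[good]
    if weights is not None:
        weights = np.asarray(weights, dtype=float)[good]
    if values.size == 0:
        return float("nan")
    edges = np.arange(vrange[0], vrange[1] + bin_width / 2, bin_width)
    hist, edges = np.histogram(values, bins=edges, weights=weights)
    i = int(np.argmax(hist))
    return float(0.5 * (edges[i] + edges[i + 1]))


def kde_mode(values, weights=None, grid_points: int = 2001, vrange=(0.0, 1.0)) -> float:
    """Alternative mode estimate from a Gaussian KDE (Scott bandwidth)."""
    from scipy.stats import gaussian_kde

    values = np.asarray(values, dtype=float)
    good = np.isfinite(values)
    values = values[good]
    if weights is not None:
        weights = np.asarray(weights, dtype=float)[good]
    kde = gaussian_kde(values, weights=weights)
    grid = np.linspace(vrange[0], vrange[1], grid_points)
    return float(grid[np.argmax(kde(grid))])
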