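"""Model classes tying the pipeline stages together.

Two estimators, in the mould of statsmodels: construct from data, call
``fit()``, get a results object carrying the estimate, its uncertainty
and full provenance.

``IntravascularSusceptometry``
    Methods I/II: Y_v of a large vein from the intravascular phase shift,
    with the geometric scaling factor either from the infinite-cylinder
    formula (Method I) or a forward field calculation of the actual
    vessel shape (Method II).

``HyperoxiaPhaseContrast``
    Method III: per-vein Y_v from the change in the intra/perivascular
    phase distribution under an isocapnic hyperoxia challenge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd

from . import forward, gas, roi
from .filters import highpass_phase
from .hyperoxia import fit_veins, weighted_mode
from .params import AcquisitionParams, BloodGasParams
from .susceptometry import (
    YvResult,
    delta_phi_iv,
    infinite_cylinder_scaling,
    yv_from_phase,
)


def _as_complex(data: np.ndarray) -> np.ndarray:
    """Interpret input as a complex volume; real input is taken to be
    phase in radians with unit magnitude."""
    data = np.asarray(data)
    if np.iscomplexobj(data):
        return data
    return np.exp(1j * data.astype(float))


class IntravascularSusceptometry:
    """Y_v from the intravascular phase of a large vein (Methods I/II).

    Parameters
    ----------
    data : ndarray
        3D complex gradient-echo volume, or a real phase volume (rad).
    sinus_mask, brain_mask : ndarray of bool
        Manually drawn vessel mask and whole-brain mask (co-registered).
    slices : sequence of int
        Indices (along ``slice_axis``) of the slices where the vessel
        runs approximately parallel to B0.
    acq : AcquisitionParams
    blood : BloodGasParams, optional
    method : {"cylinder", "forward"}
        Scaling-factor model: infinite cylinder (Method I) or forward
        field calculation of the mask shape (Method II).
    filter_d : int, optional
        Hanning high-pass diameter in k-space pixels (None = no filter).
        In the forward method the same filter (linear variant) is applied
        to the unit-susceptibility field map.
    theta : float
        Cylinder tilt to B0 in radians (Method I only).
    vein_mask : ndarray, optional
        Mask for the forward calculation; defaults to ``sinus_mask``.
    """

    def __init__(
        self,
        data,
        sinus_mask,
        brain_mask,
        slices,
        acq: AcquisitionParams,
        blood: BloodGasParams | None = None,
        method: str = "cylinder",
        filter_d: int | None = None,
        theta: float = 0.0,
        vein_mask=None,
        slice_axis: int = 2,
        tissue_correction: bool = False,
        phase_sign: int = 1,
        max_n: int = 1024,
    ):
        if method not in ("cylinder", "forward"):
            raise ValueError("method must be 'cylinder' or 'forward'")
        self.data = np.asarray(data)
        self.sinus_mask = np.asarray(sinus_mask).astype(bool)
        self.brain_mask = np.asarray(brain_mask).astype(bool)
        self.slices = list(slices)
        self.acq = acq
        self.blood = blood or BloodGasParams()
        self.method = method
        self.filter_d = filter_d
        self.theta = theta
        self.vein_mask = (
            np.asarray(vein_mask).astype(bool) if vein_mask is not None else self.sinus_mask
        )
        self.slice_axis = slice_axis
        self.tissue_correction = tissue_correction
        self.phase_sign = phase_sign
        self.max_n = max_n

    def fit(self) -> YvResult:
        if self.filter_d is not None:
            phase = highpass_phase(_as_complex(self.data), self.filter_d, axis=self.slice_axis)
        else:
            phase = np.angle(self.data) if np.iscomplexobj(self.data) else np.asarray(
                self.data, dtype=float
            )
        iv, ref = roi.build_ivref_rois(
            self.sinus_mask, self.brain_mask, self.slices, axis=self.slice_axis
        )
        dphi, se = delta_phi_iv(phase, iv, ref)
        if self.method == "cylinder":
            A = float(infinite_cylinder_scaling(self.theta))
            tag = "I"
        else:
            A = forward.scaling_factor(
                self.vein_mask,
                self.acq.direction,
                iv,
                ref,
                filter_d=self.filter_d,
                slice_axis=self.slice_axis,
                max_n=self.max_n,
            )
            tag = "II"
        result = yv_from_phase(
            dphi,
            A,
            self.acq,
            self.blood,
            method=tag,
            se_dphi=se,
            tissue_correction=self.tissue_correction,
            phase_sign=self.phase_sign,
        )
        result.flags["dphi_iv"] = dphi
        result.config = dict(
            method=self.method,
            filter_d=self.filter_d,
            theta=self.theta,
            slice_axis=self.slice_axis,
            slices=self.slices,
            n_iv=int(iv.sum()),
            n_ref=int(ref.sum()),
            tissue_correction=self.tissue_correction,
            phase_sign=self.phase_sign,
            acq=self.acq.to_dict(),
            blood=self.blood.to_dict(),
        )
        return result


@dataclass
class HyperoxiaResults:
    """Per-vein Y_v table and whole-brain summary for Method III."""

    veins: pd.DataFrame
    vein_labels: roi.VeinLabelMap
    mode: float
    dyh: float
    uncertainty: float
    config: dict = dfield(default_factory=dict)

    @property
    def yv(self) -> float:
        return self.mode

    @property
    def n_valid(self) -> int:
        return int(self.veins["valid"].sum()) if len(self.veins) else 0

    def to_result(self) -> YvResult:
        mean_a = float(self.veins.loc[self.veins.valid, "a"].mean()) if self.n_valid else float("nan")
        return YvResult(
            yv=self.mode,
            method="III",
            uncertainty=self.uncertainty,
            ancillary=mean_a,
            config=self.config,
        )

    def yv_map(self) -> np.ndarray:
        """Volume with each vein voxel carrying its vein's Y_v, NaN
        elsewhere."""
        out = np.full(self.vein_labels.labels.shape, np.nan)
        for _, row in self.veins.iterrows():
            if row.valid:
                out[self.vein_labels.labels == row.label] = row.yv
        return out

    def summary(self) -> str:
        lines = [
            "Hyperoxia phase contrast (Method III)",
            "=" * 46,
            f"veins fitted            : {len(self.veins)}",
            f"veins valid (a < 1)     : {self.n_valid}",
            f"dYh (gas model)         : {self.dyh:.4f}",
            f"Yv mode (voxel-weighted): {self.mode:.3f}",
            f"standard error          : {self.uncertainty:.4f}",
        ]
        return "\n".join(lines)

    def plot_histogram(self, ax=None, bin_width: float = 0.02):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        valid = self.veins[self.veins.valid]
        ax.hist(
            valid.yv,
            bins=np.arange(0, 1 + bin_width / 2, bin_width),
            weights=valid.n_voxels,
        )
        ax.axvline(self.mode, color="k", ls="--", label=f"mode = {self.mode:.3f}")
        ax.set_xlabel("venous oxygenation $Y_v$")
        ax.set_ylabel("voxel-weighted count")
        ax.legend()
        return ax


class HyperoxiaPhaseContrast:
    """Per-vein Y_v from paired normoxia/hyperoxia volumes (Method III).

    Parameters
    ----------
    data_no, data_ho : ndarray
        Co-registered complex (or real phase) volumes at normoxia and
        hyperoxia.
    brain_mask : ndarray of bool
    acq : AcquisitionParams
    multi_echo : roi.MultiEchoSeries, optional
        Multi-echo magnitudes for automatic vein segmentation; may be
        omitted when ``veins`` is given.
    veins : roi.VeinLabelMap, optional
        Pre-computed vein label map.
    snr : float
        Magnitude SNR; per-voxel phase error is 1/SNR on both axes.
    filter_d : int or None
        Hanning diameter applied identically to both gas states
        (default 64, the finest filter).
    dyh : float, optional
        Hyperoxia-induced change in Y_v; computed from ``blood`` via the
        gas-exchange model when omitted.
    """

    #: warn when the ramp of the inter-state phase difference exceeds
    #: this many radians across the FOV (misregistration proxy)
    RAMP_WARN_RAD = 0.5

    def __init__(
        self,
        data_no,
        data_ho,
        brain_mask,
        acq: AcquisitionParams,
        blood: BloodGasParams | None = None,
        multi_echo: roi.MultiEchoSeries | None = None,
        veins: roi.VeinLabelMap | None = None,
        snr: float = 20.0,
        filter_d: int | None = 64,
        dyh: float | None = None,
        min_points: int = 10,
        tissue_correction: bool = False,
        bin_width: float = 0.02,
        slice_axis: int = 2,
    ):
        if multi_echo is None and veins is None:
            raise ValueError("either multi_echo or veins must be provided")
        self.data_no = np.asarray(data_no)
        self.data_ho = np.asarray(data_ho)
        self.brain_mask = np.asarray(brain_mask).astype(bool)
        self.acq = acq
        self.blood = blood or BloodGasParams()
        self.multi_echo = multi_echo
        self.veins = veins
        self.snr = snr
        self.filter_d = filter_d
        self.dyh = dyh
        self.min_points = min_points
        self.tissue_correction = tissue_correction
        self.bin_width = bin_width
        self.slice_axis = slice_axis

    def _phase(self, data):
        if self.filter_d is not None:
            return highpass_phase(_as_complex(data), self.filter_d, axis=self.slice_axis)
        return np.angle(data) if np.iscomplexobj(data) else np.asarray(data, dtype=float)

    def _check_registration(self, phase_no, phase_ho):
        """Warn on a strong linear ramp in the inter-state phase
        difference (a proxy for rigid misalignment between gas states)."""
        diff = (phase_ho - phase_no)[self.brain_mask]
        coords = np.argwhere(self.brain_mask).astype(float)
        if diff.size < 100:
            return
        step = max(1, diff.size // 20000)
        c = coords[::step]
        d = diff[::step]
        X = np.column_stack([np.ones(len(c)), c / np.maximum(c.max(axis=0), 1)])
        beta, *_ = np.linalg.lstsq(X, d, rcond=None)
        ramp = float(np.abs(beta[1:]).sum())
        if ramp > self.RAMP_WARN_RAD:
            warnings.warn(
                f"phase-difference ramp of {ramp:.2f} rad across the FOV "
                "between gas states: check registration",
                stacklevel=3,
            )

    def fit(self) -> HyperoxiaResults:
        dyh = self.dyh if self.dyh is not None else gas.delta_yh(self.blood)
        phase_no = self._phase(self.data_no)
        phase_ho = self._phase(self.data_ho)
        self._check_registration(phase_no, phase_ho)
        veins = self.veins
        if veins is None:
            r2s = roi.r2star_map(self.multi_echo)
            veins = roi.segment_veins(r2s, self.brain_mask, axis=self.slice_axis)
        table = fit_veins(
            phase_no,
            phase_ho,
            veins,
            snr=self.snr,
            dyh=dyh,
            blood=self.blood,
            min_points=self.min_points,
            tissue_correction=self.tissue_correction,
        )
        valid = table[table.valid] if len(table) else table
        if len(valid):
            mode = weighted_mode(valid.yv, weights=valid.n_voxels, bin_width=self.bin_width)
            w = valid.n_voxels.to_numpy(dtype=float)
            yvv = valid.yv.to_numpy(dtype=float)
            wmean = float(np.average(yvv, weights=w))
            wvar = float(np.average((yvv - wmean) ** 2, weights=w))
            se = float(np.sqrt(wvar / len(valid))) if len(valid) > 1 else float(valid.se_yv.iloc[0])
        else:
            warnings.warn("no valid veins: empty Method III result", stacklevel=2)
            mode = float("nan")
            se = float("nan")
        config = dict(
            filter_d=self.filter_d,
            snr=self.snr,
            dyh=dyh,
            min_points=self.min_points,
            bin_width=self.bin_width,
            slice_axis=self.slice_axis,
            tissue_correction=self.tissue_correction,
            n_veins=len(table),
            acq=self.acq.to_dict(),
            blood=self.blood.to_dict(),
        )
        return HyperoxiaResults(
            veins=table,
            vein_labels=veins,
            mode=mode,
            dyh=dyh,
            uncertainty=se,
            config=config,
        )
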