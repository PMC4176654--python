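"""ROI construction, R2* mapping and automatic vein segmentation.

Methods I/II use a ring-reference construction around a manually drawn
sinus mask (per-slice 2D morphology); Method III identifies veins
automatically from a multi-echo R2* map (veins have elevated R2* from
deoxyhaemoglobin), labels them by 26-connectivity, discards very large
clusters (the inter-hemispheric fissure) and dilates each vein by one
voxel to form its fit ROI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import constants

#: Named 2D (per-slice) structuring-element sizes and the single 3D one.
KERNELS_2D = {"3x3": 3, "5x5": 5, "7x7": 7, "11x11": 11}
KERNEL_3D = "3x3x3"


@dataclass
class MultiEchoSeries:
    """A multi-echo gradient-echo magnitude series.

    ``magnitudes`` is a list of >= 2 same-shaped, non-negative 3D volumes
    at strictly ascending echo times ``tes`` (seconds).
    """

    magnitudes: list
    tes: list

    def __post_init__(self):
        if len(self.magnitudes) < 2:
            raise ValueError("at least 2 echoes are required")
        if len(self.magnitudes) != len(self.tes):
            raise ValueError("one echo time per magnitude volume")
        shapes = {np.asarray(m).shape for m in self.magnitudes}
        if len(shapes) != 1:
            raise ValueError("all echo volumes must share a shape")
        tes = np.asarray(self.tes, dtype=float)
        if np.any(np.diff(tes) <= 0):
            raise ValueError("echo times must be strictly ascending")
        if any(np.any(np.asarray(m) < 0) for m in self.magnitudes):
            raise ValueError("magnitudes must be non-negative")


@dataclass
class VeinLabelMap:
    """Labelled vein clusters with per-vein dilated fit ROIs.

    ``labels`` is 0 for background and 1..n_veins in a fixed scan order
    (lexicographic first voxel).  ``rois[i]`` is the boolean fit mask of
    label ``i + 1`` and is a superset of that label's voxels.
    """

    labels: np.ndarray
    rois: list = field(default_factory=list)
    sizes: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    @property
    def n_veins(self) -> int:
        return len(self.rois)


def structuring_element(kernel: str, axis: int = 2) -> np.ndarray:
    """Build the named structuring element; 2D kernels act per slice
    (the plane perpendicular to ``axis``), the 3x3x3 kernel acts in 3D."""
    if kernel == KERNEL_3D:
        return np.ones((3, 3, 3), dtype=bool)
    if kernel not in KERNELS_2D:
        raise ValueError(f"unknown kernel {kernel!r}; use one of "
                         f"{sorted(KERNELS_2D)} or '3x3x3'")
    k = KERNELS_2D[kernel]
    shape = [k, k, k]
    shape[axis] = 1
    return np.ones(shape, dtype=bool)


def morph(mask: np.ndarray, op: str, kernel: str, axis: int = 2) -> np.ndarray:
    """Binary erosion or dilation with a named structuring element."""
    mask = np.asarray(mask).astype(bool)
    structure = structuring_element(kernel, axis=axis)
    if op == "erode":
        return ndimage.binary_erosion(mask, structure=structure)
    if op == "dilate":
        return ndimage.binary_dilation(mask, structure=structure)
    raise ValueError(f"unknown morphology op {op!r}")


def r2star_map(series: MultiEchoSeries) -> np.ndarray:
    """Voxel-wise R2* (s^-1) by linear regression of -ln(S) on TE.

    Voxels with any non-positive magnitude are flagged invalid (NaN) and
    excluded downstream.  Invariant to global magnitude scaling.
    """
    mags = np.stack([np.asarray(m, dtype=float) for m in series.magnitudes])
    tes = np.asarray(series.tes, dtype=float)
    valid = np.all(mags > 0, axis=0)
    logs = np.log(np.where(mags > 0, mags, 1.0))
    t = tes - tes.mean()
    slope = np.tensordot(t, logs, axes=(0, 0)) / (t @ t)
    r2s = -slope
    r2s[~valid] = np.nan
    return r2s


def build_ivref_rois(
    sinus_mask: np.ndarray,
    brain_mask: np.ndarray,
    slices,
    axis: int = 2,
):
    """Intravascular and ring-reference ROIs from the sinus mask.

    iv = erode(sinus, 3x3); ref = dilate(sinus, 5x5) - dilate(sinus, 3x3);
    both restricted to the selected slices (chosen where the vessel runs
    approximately parallel to B0) and to the brain mask eroded by 7x7 (to
    exclude spatial-filter edge artefacts).  The ROIs are disjoint by
    construction.
    """
    sinus = np.asarray(sinus_mask).astype(bool)
    brain = np.asarray(brain_mask).astype(bool)
    if sinus.shape != brain.shape:
        raise ValueError("sinus and brain masks must share a shape")
    slice_sel = np.zeros(sinus.shape, dtype=bool)
    idx = [slice(None)] * 3
    idx[axis] = np.asarray(list(slices), dtype=int)
    slice_sel[tuple(idx)] = True

    brain_er = morph(brain, "erode", "7x7", axis=axis)
    iv = morph(sinus, "erode", "3x3", axis=axis) & slice_sel & brain_er
    ring = morph(sinus, "dilate", "5x5", axis=axis) & ~morph(
        sinus, "dilate", "3x3", axis=axis
    )
    ref = ring & slice_sel & brain_er

    for s in slices:
        sel = [slice(None)] * 3
        sel[axis] = s
        sel = tuple(sel)
        if not iv[sel].any() or not ref[sel].any():
            warnings.warn(
                f"slice {s}: empty ROI (iv={int(iv[sel].sum())}, "
                f"ref={int(ref[sel].sum())})",
                stacklevel=2,
            )
    if not iv.any() or not ref.any():
        raise ValueError("ROI construction produced an empty ROI")
    return iv, ref


def segment_veins(
    r2s: np.ndarray,
    brain_mask: np.ndarray,
    threshold: float = constants.R2S_VEIN_THRESHOLD,
    max_cluster_voxels: int = constants.CLUSTER_MAX_VOXELS,
    axis: int = 2,
) -> VeinLabelMap:
    """Automatic vein segmentation from an R2* map.

    Threshold ``r2s > threshold`` within the brain mask eroded by 11x11
    (5 voxels, excluding filter edge artefacts); label connected
    components under 26-connectivity; discard components of
    ``max_cluster_voxels`` or more voxels (inter-hemispheric fissure);
    each surviving vein's fit ROI is its component dilated by one voxel
    (3x3x3), clipped to the eroded brain mask.  Labelling order follows
    the lexicographic first voxel, so the result is deterministic.
    """
    r2s = np.asarray(r2s, dtype=float)
    brain_er = morph(np.asarray(brain_mask).astype(bool), "erode", "11x11", axis=axis)
    with np.errstate(invalid="ignore"):
        binary = (r2s > threshold) & brain_er & np.isfinite(r2s)
    labels, n = ndimage.label(binary, structure=np.ones((3, 3, 3), dtype=bool))
    out_labels = np.zeros_like(labels)
    rois: list = []
    sizes: list = []
    if n:
        flat = labels.ravel()
        counts = np.bincount(flat, minlength=n + 1)
        vals, first = np.unique(flat, return_index=True)
        first_index = dict(zip(vals.tolist(), first.tolist()))
        kept = [lab for lab in range(1, n + 1) if counts[lab] < max_cluster_voxels]
        kept.sort(key=lambda lab: first_index[lab])
        for new, lab in enumerate(kept, start=1):
            comp = labels == lab
            out_labels[comp] = new
            roi = ndimage.binary_dilation(
                comp, structure=np.ones((3, 3, 3), dtype=bool)
            ) & brain_er
            rois.append(roi)
            sizes.append(int(counts[lab]))
    if not rois:
        warnings.warn("no vein clusters survived segmentation", stacklevel=2)
    return VeinLabelMap(labels=out_labels, rois=rois, sizes=np.asarray(sizes, dtype=int))
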