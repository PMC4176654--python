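"""Forward field calculation for an arbitrary vessel shape (Method II).

The field perturbation of a susceptibility distribution ``chi(r)`` in a
uniform field B0 along unit vector ``e`` is computed by multiplication in
k-space with the point-dipole kernel

    D(k) = 1/3 - (k . e)^2 / |k|^2,      D(0) := 0.

Applied to a binary vessel mask with unit susceptibility this yields a
dimensionless map ``a(r) = dB(r) / (B0 * dchi)``; the vessel-specific
scaling factor ``A`` is the difference of the (identically filtered) map
between the intravascular and reference ROIs.  For a long cylinder
parallel to B0 the interior of this map approaches the analytic 1/3.

To keep FFT aliasing away from the region of interest the mask is
zero-padded to an N^3 cube centred on the vessel ROI, with N at least
twice the ROI extent and large enough to contain the whole original
matrix (so that unpadding returns a seamless map on the original grid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import fftn, ifftn, next_fast_len

from .filters import highpass_linear


@dataclass
class PaddedGrid:
    """A volume embedded in an N^3 zero-padded cube.

    ``offset`` locates the original volume inside the cube; ``unpad``
    extracts the original region from any array on the padded grid.
    """

    data: np.ndarray
    offset: tuple
    n: int
    original_shape: tuple

    def unpad(self, arr: np.ndarray | None = None) -> np.ndarray:
        if arr is None:
            arr = self.data
        sl = tuple(
            slice(o, o + s) for o, s in zip(self.offset, self.original_shape)
        )
        return arr[sl]


def roi_bbox(mask: np.ndarray):
    """Inclusive (lo, hi) index bounds of the nonzero region, per axis."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    idx = np.nonzero(mask)
    return [(int(a.min()), int(a.max())) for a in idx]


def pad_for_fft(mask: np.ndarray, bbox=None, max_n: int = 1024) -> PaddedGrid:
    """Zero-pad a volume to an FFT-friendly N^3 cube centred on the ROI.

    N is at least twice the largest ROI extent, contains the entire
    original matrix, and is rounded up to an FFT-efficient length.
    ``unpad(pad(x)) == x`` exactly.
    """
    mask = np.asarray(mask)
    if bbox is None:
        bbox = roi_bbox(mask)
    shape = mask.shape
    centre = [(lo + hi) // 2 for lo, hi in bbox]
    extent = max(hi - lo + 1 for lo, hi in bbox)
    n_min = 2 * extent
    for c, s in zip(centre, shape):
        n_min = max(n_min, 2 * c + 2, 2 * (s - c))
    while True:
        n = next_fast_len(n_min)
        offset = [n // 2 - c for c in centre]
        if all(o >= 0 and o + s <= n for o, s in zip(offset, shape)):
            break
        n_min = n + 1
    if n > max_n:
        raise MemoryError(
            f"forward calculation requires an N={n} padded cube, above the "
            f"budget max_n={max_n}; increase max_n if memory allows"
        )
    data = np.zeros((n, n, n), dtype=mask.dtype)
    sl = tuple(slice(o, o + s) for o, s in zip(offset, shape))
    data[sl] = mask
    return PaddedGrid(data=data, offset=tuple(offset), n=n, original_shape=shape)


def dipole_kernel(shape, field_direction, voxel_size=(1.0, 1.0, 1.0)) -> np.ndarray:
    """k-space dipole kernel ``1/3 - k_par^2/|k|^2`` on an unshifted grid.

    The k = 0 sample is set to 0, referencing the field to its spatial
    mean over the (padded) grid; any downstream ROI difference is
    insensitive to this choice.
    """
    e = np.asarray(field_direction, dtype=float)
    if abs(np.linalg.norm(e) - 1.0) > 1e-9:
        raise ValueError("field_direction must be a unit vector")
    freqs = [
        np.fft.fftfreq(s, d=v).astype(float) for s, v in zip(shape, voxel_size)
    ]
    kx = freqs[0][:, None, None]
    ky = freqs[1][None, :, None]
    kz = freqs[2][None, None, :]
    k2 = kx * kx + ky * ky + kz * kz
    kpar = kx * e[0] + ky * e[1] + kz * e[2]
    with np.errstate(divide="ignore", invalid="ignore"):
        kernel = 1.0 / 3.0 - (kpar * kpar) / k2
    kernel[0, 0, 0] = 0.0
    return kernel


def dipole_field(chi: np.ndarray, field_direction, voxel_size=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Field perturbation of a susceptibility map, in units of B0 * chi.

    Linear in ``chi``; the spatial mean of the result is zero (k = 0
    kernel sample is zero).
    """
    chi = np.asarray(chi, dtype=float)
    kernel = dipole_kernel(chi.shape, field_direction, voxel_size)
    return ifftn(fftn(chi) * kernel).real


def field_map(
    mask: np.ndarray,
    field_direction,
    voxel_size=(1.0, 1.0, 1.0),
    max_n: int = 1024,
) -> np.ndarray:
    """Unit-susceptibility forward-field map of a binary vessel mask,
    computed on the padded grid and returned on the original grid."""
    padded = pad_for_fft(np.asarray(mask, dtype=float), max_n=max_n)
    fld = dipole_field(padded.data, field_direction, voxel_size)
    return padded.unpad(fld)


def scaling_factor(
    mask: np.ndarray,
    field_direction,
    iv_roi: np.ndarray,
    ref_roi: np.ndarray,
    filter_d: float | None = None,
    voxel_size=(1.0, 1.0, 1.0),
    slice_axis: int = 2,
    a_map: np.ndarray | None = None,
    max_n: int = 1024,
) -> float:
    """Vessel-specific scaling factor A (Method II).

    ``A = mean(a_map over iv_roi) - mean(a_map over ref_roi)`` where the
    unit-susceptibility field map receives the same Hanning high-pass
    filter (linear variant, diameter ``filter_d``) as the phase data.
    A precomputed ``a_map`` may be supplied to skip the forward step.
    """
    iv_roi = np.asarray(iv_roi, dtype=bool)
    ref_roi = np.asarray(ref_roi, dtype=bool)
    if not iv_roi.any() or not ref_roi.any():
        raise ValueError("empty ROI in scaling_factor")
    if a_map is None:
        a_map = field_map(mask, field_direction, voxel_size, max_n=max_n)
    if filter_d is not None:
        a_map = highpass_linear(a_map, filter_d, axis=slice_axis)
    return float(a_map[iv_roi].mean() - a_map[ref_roi].mean())
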