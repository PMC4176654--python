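"""Complex 2D Hanning k-space filtering of phase data.

Large-scale phase variation from external field sources (shim, air/tissue
interfaces, hyperoxic gas in the sinuses) is removed by high-pass
filtering each 2D slice in k-space with a radially symmetric Hanning
window of diameter ``d`` samples.  Two variants are provided:

``highpass_phase``
    The homodyne form for complex image data: the complex slice is divided
    by its low-pass-filtered version and the angle taken.  This tolerates
    phase wraps in the slowly varying background.

``highpass_linear``
    The subtractive form for real-valued maps (e.g. the unit-susceptibility
    forward-field map): slice minus its low-pass.  Strictly linear in the
    input, which keeps the vessel-specific scaling factor linear in the
    susceptibility.

Larger ``d`` means a wider low-pass window, hence a *finer* high-pass
filter that removes structure above a smaller spatial scale.
"""

from __future__ import annotations

import numpy as np


def hanning_window(d: float, shape: tuple) -> np.ndarray:
    """Radially symmetric Hanning low-pass window in centred k-space.

    ``w(r) = 0.5 * (1 + cos(2*pi*r/d))`` for k-space radius ``r < d/2``,
    zero outside; ``r`` is measured in k-space samples from the DC sample
    (placed at ``n // 2`` after an FFT shift).

    Parameters
    ----------
    d : float
        Window diameter in k-space pixels.
    shape : tuple of int
        2D slice dimensions.

    Returns
    -------
    ndarray
        The window on the centred (fftshifted) k-space grid.
    """
    if len(shape) != 2:
        raise ValueError("shape must be 2D")
    if d <= 0 or d > min(shape):
        raise ValueError(f"window diameter d={d} must lie in (0, min(shape)={min(shape)}]")
    i = np.arange(shape[0]) - shape[0] // 2
    j = np.arange(shape[1]) - shape[1] // 2
    r = np.hypot(i[:, None], j[None, :])
    w = 0.5 * (1.0 + np.cos(2.0 * np.pi * r / d))
    w[r >= d / 2.0] = 0.0
    return w


def _lowpass_slice(slc: np.ndarray, window: np.ndarray) -> np.ndarray:
    f = np.fft.fftshift(np.fft.fft2(slc))
    return np.fft.ifft2(np.fft.ifftshift(f * window))


def highpass_phase(
    complex_vol: np.ndarray,
    d: float,
    axis: int = 2,
    return_flags: bool = False,
):
    """High-pass filter the phase of a complex volume (homodyne form).

    Per 2D slice perpendicular to ``axis``: the low-pass image is the
    inverse FT of the windowed spectrum, and the filtered phase is
    ``angle(slice / lowpass)``, in (-pi, pi].  Voxels where the low-pass
    magnitude is exactly zero get filtered phase 0 and are flagged.

    Parameters
    ----------
    complex_vol : ndarray, complex
        3D complex (magnitude * exp(i*phase)) volume, or a 2D slice.
    d : float
        Hanning window diameter in k-space pixels.
    axis : int
        Slice axis (slices are taken perpendicular to it).
    return_flags : bool
        If True also return the boolean map of zero-low-pass voxels.
    """
    vol = np.asarray(complex_vol)
    squeeze = vol.ndim == 2
    if squeeze:
        vol = vol[..., None]
        axis = 2
    moved = np.moveaxis(vol, axis, -1)
    out = np.empty(moved.shape, dtype=float)
    flags = np.zeros(moved.shape, dtype=bool)
    window = hanning_window(d, moved.shape[:2])
    for k in range(moved.shape[-1]):
        lp = _lowpass_slice(moved[..., k], window)
        bad = lp == 0
        safe = np.where(bad, 1.0, lp)
        ph = np.angle(moved[..., k] / safe)
        ph[bad] = 0.0
        out[..., k] = ph
        flags[..., k] = bad
    out = np.moveaxis(out, -1, axis)
    flags = np.moveaxis(flags, -1, axis)
    if squeeze:
        out = out[..., 0]
        flags = flags[..., 0]
    if return_flags:
        return out, flags
    return out


def highpass_linear(real_map: np.ndarray, d: float, axis: int = 2) -> np.ndarray:
    """High-pass filter a real-valued map (subtractive, linear form).

    Per 2D slice: ``map - IFT(FT(map) * window)``.  Linear in the input;
    the DC component is removed exactly (the window is 1 at DC).
    """
    vol = np.asarray(real_map, dtype=float)
    squeeze = vol.ndim == 2
    if squeeze:
        vol = vol[..., None]
        axis = 2
    moved = np.moveaxis(vol, axis, -1)
    out = np.empty_like(moved)
    window = hanning_window(d, moved.shape[:2])
    for k in range(moved.shape[-1]):
        out[..., k] = moved[..., k] - _lowpass_slice(moved[..., k], window).real
    out = np.moveaxis(out, -1, axis)
    if squeeze:
        out = out[..., 0]
    return out
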