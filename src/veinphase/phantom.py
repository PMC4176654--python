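"""Synthetic phantoms for every stage of the pipeline.

A paramagnetic vessel (straight cylinder, analytic field; or a curved
tube, field from the k-space forward model) is embedded in a uniform
tissue background.  The generator emits everything the in-vivo protocol
would provide: complex gradient-echo volumes at normoxia and hyperoxia
differing only by a known dYh, slowly varying polynomial background
phase, complex Gaussian noise at a stated magnitude SNR, binary masks,
and a multi-echo magnitude series with elevated R2* inside the vein so
that the R2* > 100 s^-1 threshold segments the vessel.

Analytic cylinder field (units of B0 * dchi), tilt theta to B0:

    interior:  (3 cos^2 theta - 1) / 6
    exterior:  (sin^2 theta / 2) * (a^2 / rho^2) * cos(2 phi)

with rho, phi cylinder-centred polar coordinates; the exterior field
vanishes for a vessel parallel to B0.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from . import forward
from .params import AcquisitionParams, BloodGasParams


@dataclass
class PhantomSpec:
    """Ground-truth description of a synthetic vessel phantom.

    Defaults reflect the acquisition the package targets: 7 T, TE = 5 ms,
    0.65 mm isotropic voxels, magnitude SNR 20, haematocrit 0.4.  The
    multi-echo series used for vein identification is a separate
    acquisition and carries its own SNR (default 50); vein / tissue R2*
    defaults (150 / 30 s^-1) straddle the 100 s^-1 segmentation
    threshold.
    """

    shape: tuple = (128, 128, 128)
    voxel_size_mm: float = 0.65
    axis: tuple = (0.0, 0.0, 1.0)
    center: tuple | None = None
    radius: float = 4.0          # voxels
    length: float | None = None  # voxels along the axis; None = full grid
    polyline: list | None = None  # curved vessel centreline, voxel coords
    yv_true: float = 0.62
    dyh_true: float = 0.066
    blood: BloodGasParams = dfield(default_factory=BloodGasParams)
    acq: AcquisitionParams = dfield(default_factory=lambda: AcquisitionParams(te=5e-3, b0=7.0))
    snr: float | None = 20.0
    mecho_snr: float | None = 50.0
    tes: tuple = (5e-3, 10e-3, 15e-3)
    r2s_vein: float = 150.0
    r2s_tissue: float = 30.0
    background: dict | None = None     # {(i,j,k): coeff} polynomial, rad
    background_ho: dict | None = None  # hyperoxia-specific background; None = same
    seed: int | None = 0

    def __post_init__(self):
        if self.radius < 1:
            raise ValueError("vessel radius must be >= 1 voxel")
        if not 0 < self.yv_true < 1:
            raise ValueError("yv_true must lie in (0, 1)")
        if not 0 <= self.dyh_true < 1 - self.yv_true:
            raise ValueError("dyh_true must lie in [0, 1 - yv_true)")

    @property
    def centre(self) -> np.ndarray:
        if self.center is not None:
            return np.asarray(self.center, dtype=float)
        return (np.asarray(self.shape, dtype=float) - 1.0) / 2.0

    def dchi(self, yv: float) -> float:
        """Vein-tissue susceptibility difference at oxygenation ``yv``."""
        return self.blood.hct * (1.0 - yv) * self.blood.dchi_do


def _cylinder_coords(spec: PhantomSpec):
    """Perpendicular distance rho and azimuth phi (from the projected B0
    direction) of every voxel relative to the cylinder axis, plus the
    axial coordinate s and cos(theta) of the axis-B0 tilt."""
    n = np.asarray(spec.axis, dtype=float)
    n = n / np.linalg.norm(n)
    z = spec.acq.direction
    cos_theta = float(np.dot(n, z))
    e1 = z - cos_theta * n
    if np.linalg.norm(e1) < 1e-12:
        # axis parallel to B0: azimuth reference is arbitrary (sin theta = 0)
        e1 = np.array([1.0, 0.0, 0.0])
        e1 = e1 - np.dot(e1, n) * n
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(n, e1)

    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in spec.shape], indexing="ij")
    p = [g - c for g, c in zip(grids, spec.centre)]
    s = p[0] * n[0] + p[1] * n[1] + p[2] * n[2]
    perp = [p[i] - s * n[i] for i in range(3)]
    c1 = perp[0] * e1[0] + perp[1] * e1[1] + perp[2] * e1[2]
    c2 = perp[0] * e2[0] + perp[1] * e2[1] + perp[2] * e2[2]
    rho = np.hypot(c1, c2)
    phi = np.arctan2(c2, c1)
    return rho, phi, s, cos_theta


def vessel_mask(spec: PhantomSpec) -> np.ndarray:
    """Binary mask of the vessel (straight cylinder or polyline tube)."""
    if spec.polyline is not None:
        return _tube_mask(spec)
    rho, _, s, _ = _cylinder_coords(spec)
    mask = rho <= spec.radius
    if spec.length is not None:
        mask &= np.abs(s) <= spec.length / 2.0
    return mask


def cylinder_unit_field(spec: PhantomSpec) -> np.ndarray:
    """Analytic infinite-cylinder field map in units of B0 * dchi."""
    rho, phi, s, cos_theta = _cylinder_coords(spec)
    sin2 = 1.0 - cos_theta * cos_theta
    interior = rho <= spec.radius
    out = np.where(
        interior,
        (3.0 * cos_theta * cos_theta - 1.0) / 6.0,
        0.5 * sin2 * (spec.radius ** 2 / np.where(interior, 1.0, rho) ** 2)
        * np.cos(2.0 * phi),
    )
    return out


def cylinder_field(spec: PhantomSpec) -> np.ndarray:
    """Analytic cylinder field in tesla at the normoxic oxygenation."""
    return spec.acq.b0 * spec.dchi(spec.yv_true) * cylinder_unit_field(spec)


def _tube_mask(spec: PhantomSpec) -> np.ndarray:
    pts = np.asarray(spec.polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ValueError("polyline must be an (n>=2, 3) array of voxel coords")
    if np.any(pts < 0) or np.any(pts >= np.asarray(spec.shape)):
        raise ValueError("polyline must lie inside the grid")
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in spec.shape], indexing="ij")
    pos = np.stack(grids, axis=-1)
    dist2 = np.full(spec.shape, np.inf)
    for a, b in zip(pts[:-1], pts[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            continue
        t = np.clip(((pos - a) @ ab) / denom, 0.0, 1.0)
        closest = a + t[..., None] * ab
        d2 = np.sum((pos - closest) ** 2, axis=-1)
        dist2 = np.minimum(dist2, d2)
    return dist2 <= spec.radius ** 2


def background_phase(spec: PhantomSpec, coeffs: dict | None) -> np.ndarray:
    """Slowly varying polynomial phase; coords normalised to [-1, 1].

    ``coeffs`` maps exponent triples (i, j, k), each total order <= 3,
    to coefficients in radians.
    """
    out = np.zeros(spec.shape)
    if not coeffs:
        return out
    axes = [2.0 * np.arange(s) / max(s - 1, 1) - 1.0 for s in spec.shape]
    u, v, w = np.meshgrid(*axes, indexing="ij")
    for (i, j, k), c in coeffs.items():
        if i + j + k > 3:
            raise ValueError("background polynomial order is limited to 3")
        out += c * u ** i * v ** j * w ** k
    return out


def _unit_field(spec: PhantomSpec) -> np.ndarray:
    """Dimensionless field map (per B0*dchi): analytic for a straight
    cylinder, forward model for a polyline tube."""
    if spec.polyline is None:
        return cylinder_unit_field(spec)
    mask = _tube_mask(spec)
    return forward.field_map(mask, spec.acq.direction)


def make_pair(spec: PhantomSpec) -> dict:
    """Generate a matched normoxia/hyperoxia bundle.

    Returns a dict with complex volumes (``complex_no``/``complex_ho``),
    their noisy phases, the multi-echo magnitude list and echo times,
    vessel and brain masks, and a ``truth`` record carrying every
    ground-truth parameter.  Seeded generation is bit-reproducible.

    Raises if the noiseless phase reaches +/-pi anywhere (a wrapped
    phantom would silently corrupt every downstream estimate).
    """
    unit = _unit_field(spec)
    gamma_te_b0 = spec.acq.gamma * spec.acq.te * spec.acq.b0
    dchi_no = spec.dchi(spec.yv_true)
    dchi_ho = spec.dchi(spec.yv_true + spec.dyh_true)
    bg_no = background_phase(spec, spec.background)
    bg_ho = background_phase(
        spec, spec.background_ho if spec.background_ho is not None else spec.background
    )
    phi_no = gamma_te_b0 * dchi_no * unit + bg_no
    phi_ho = gamma_te_b0 * dchi_ho * unit + bg_ho

    for name, ph, bg, dchi in (("normoxia", phi_no, bg_no, dchi_no),
                               ("hyperoxia", phi_ho, bg_ho, dchi_ho)):
        peak = float(np.max(np.abs(ph)))
        if peak >= np.pi:
            vessel_peak = gamma_te_b0 * dchi * float(np.max(np.abs(unit)))
            bg_peak = float(np.max(np.abs(bg)))
            offender = "background coefficients" if bg_peak > vessel_peak else (
                "yv_true/dyh_true (vessel susceptibility contrast)")
            raise ValueError(
                f"{name} phase wraps (|phi| max {peak:.2f} >= pi); "
                f"offending parameter: {offender}"
            )

    rng = np.random.default_rng(spec.seed)

    def _noisy_complex(phi):
        c = np.exp(1j * phi)
        if spec.snr is not None and np.isfinite(spec.snr):
            sigma = 1.0 / spec.snr
            c = c + sigma * (rng.standard_normal(c.shape)
                             + 1j * rng.standard_normal(c.shape))
        return c

    c_no = _noisy_complex(phi_no)
    c_ho = _noisy_complex(phi_ho)

    vmask = vessel_mask(spec)
    brain = np.ones(spec.shape, dtype=bool)
    r2s = np.where(vmask, spec.r2s_vein, spec.r2s_tissue)
    mags = []
    for te in spec.tes:
        m = np.exp(-r2s * te).astype(complex)
        if spec.mecho_snr is not None and np.isfinite(spec.mecho_snr):
            sig = 1.0 / spec.mecho_snr
            m = m + sig * (rng.standard_normal(spec.shape)
                           + 1j * rng.standard_normal(spec.shape))
        mags.append(np.abs(m))

    truth = dict(
        yv_true=spec.yv_true,
        dyh_true=spec.dyh_true,
        dchi_no=dchi_no,
        dchi_ho=dchi_ho,
        a_true=dchi_ho / dchi_no if dchi_no else np.nan,
        snr=spec.snr,
        mecho_snr=spec.mecho_snr,
        r2s_vein=spec.r2s_vein,
        r2s_tissue=spec.r2s_tissue,
        te=spec.acq.te,
        b0=spec.acq.b0,
        gamma=spec.acq.gamma,
        hct=spec.blood.hct,
        dchi_do=spec.blood.dchi_do,
        seed=spec.seed,
    )
    return dict(
        phase_no=np.angle(c_no),
        phase_ho=np.angle(c_ho),
        complex_no=c_no,
        complex_ho=c_ho,
        phi_no_clean=phi_no,
        phi_ho_clean=phi_ho,
        magnitudes=mags,
        tes=list(spec.tes),
        vessel_mask=vmask,
        brain_mask=brain,
        truth=truth,
    )


def curved_vessel_phantom(spec: PhantomSpec) -> dict:
    """``make_pair`` for a polyline-centreline vessel (field from the
    k-space forward model rather than the analytic cylinder)."""
    if spec.polyline is None:
        raise ValueError("curved_vessel_phantom requires spec.polyline")
    return make_pair(spec)
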