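# Methods

This note documents the models implemented in `veinphase`, the choices
made where the underlying methodology leaves room, and what the
synthetic phantoms do and do not establish about real data.

## Physical model

A vein with haematocrit Hct and oxygen saturation Y_v differs in volume
susceptibility from tissue by Δχ_IV = Hct·(1 − Y_v)·Δχ_do, assuming
tissue shares the susceptibility of fully oxygenated haemoglobin.
Δχ_do = 3.32×10⁻⁶ (SI; the cgs value 0.264×10⁻⁶ differs by 4π — a
classic source of error, guarded by a unit-conversion test).  The
induced field shift inside the vessel is ΔB = A·B0·Δχ_IV with a
geometry factor A, and the gradient-echo phase is φ = γ·ΔB·TE.

Sign convention: a paramagnetic (deoxygenated) vein parallel to B0
produces *positive* intravascular phase.  Phantoms and estimators share
this constant; `phase_sign=-1` flips it for scanners with the opposite
convention.  γ = 2.6752218744×10⁸ rad s⁻¹ T⁻¹ (CODATA proton value) is a
named, overridable constant.

### Tissue-susceptibility correction

Dropping the tissue ≡ oxyhaemoglobin assumption adds Hct·Y_v·Δχ_oxy to
Δχ_IV (Δχ_oxy = −0.21×10⁻⁶ SI, oxyhaemoglobin vs water).  The default
corrected inversion adds Δχ_oxy/Δχ_do ≈ −0.063 to Y_v — an additive
form that is exact only when Y_v ≈ 1 inside the correction term.  The
exact inversion of the corrected relation,
Y_v = (1 − Δχ_IV/(Hct·Δχ_do)) / (1 − Δχ_oxy/Δχ_do), is available as
`correction_form="exact"`; the additive form is the default because it
is the standard statement of the correction.

## Spatial filtering

Large-scale background phase (shim, air/tissue interfaces, hyperoxic
gas in the sinuses) is removed by a radially symmetric Hanning window
of diameter D ∈ {16, 32, 64} k-space pixels, applied per 2D slice.
Two constructions are used deliberately:

- complex (homodyne) division for phase data — tolerant of wraps in the
  background;
- linear subtraction for real-valued field maps — keeps the Method II
  scaling map strictly linear in susceptibility (a complex encoding of a
  unit-susceptibility map would wrap catastrophically).

Larger D removes structure above a smaller spatial scale, so D = 64 is
the *finest* filter.  Filtering is applied slice-by-slice along the
stored third axis by default (configurable), matching the acquisition
geometry.  FFT periodicity produces an edge band of artefact; all ROI
logic therefore intersects with an eroded brain mask (7×7 for the
intravascular methods, 11×11 for vein segmentation).

A consequence quantified by the phantom tests: the homodyne high-pass is
slightly nonlinear at the phase amplitudes a 7 T, TE = 5 ms vein
produces (|φ| up to ~2 rad), biasing the Method III slope upward by
~0.01 at D = 64 even without noise (Y_v low by ~0.02).  The identical
filtering of normoxia and hyperoxia data keeps the bias small, but it is
inherent to high-pass filtering of nonlinear phase.

## Method II forward field calculation

The field of the binary vessel mask with unit susceptibility is computed
by k-space multiplication with the dipole kernel 1/3 − (k·ê)²/|k|².
Numerical choices:

- the mask is zero-padded to an N³ cube, N ≥ 2× the largest ROI extent,
  centred on the ROI and containing the whole original matrix (so the
  unpadded map is seamless for subsequent filtering); N is rounded up to
  an FFT-efficient length;
- the k = 0 kernel sample is set to 0 (field referenced to its spatial
  mean); the intravascular-minus-reference difference that defines A is
  insensitive to this choice, asserted by test;
- the field direction is supplied as a unit vector in image coordinates
  — the user composes scanner angles with any registration transform;
- binary voxel masks are used without sub-voxel surface smoothing.

On 128³ grids with vessel aspect ratio ≥ 10 the forward field matches
the analytic infinite-cylinder interior (1/3 parallel, −1/6
perpendicular) to ~1.2 %, and a sphere's exterior matches the point
dipole a³(3cos²θ−1)/(3r³) to ~1 %.

## ROI construction and vein segmentation

Methods I/II: the intravascular ROI is the sinus mask eroded by one
voxel (3×3, per slice); the reference ROI is a ring, dilate(5×5) minus
dilate(3×3); both restricted to five user-selected slices where the
vessel is parallel to B0 and to the brain mask eroded by 7×7.  Each
erosion/dilation count is one application of the named element, not an
iteration.

Method III: R2* is fitted voxel-wise by unweighted least squares of
−ln(S) on TE (3 echoes; noise-floor weighting is out of scope at this
echo count); veins are voxels with R2* > 100 s⁻¹ inside the brain mask
eroded by 11×11.  "Clustering with a 3×3×3 kernel" is implemented as
connected-component labelling under the 26-connectivity that kernel
defines.  Components of ≥ 1200 voxels are discarded (they are the
inter-hemispheric fissure in practice; the threshold is configurable),
and each vein's fit ROI is its component dilated by one voxel (3×3×3).
Labelling follows lexicographic first-voxel order, so results are
deterministic.

## Gas-exchange model and York fit

ΔY_h = ΔSaO2 + ε·ΔPaO2/(ψ·[Hb]) with ψ = 1.34 ml/g, [Hb] = 15 g/dl,
ε = 0.0031 ml/dl/mmHg, SaO2(PaO2) from the Severinghaus curve
SaO2 = (23400/(PaO2³ + 150·PaO2) + 1)⁻¹, and PaO2 taken equal to
end-tidal PO2 (reasonable for prospective end-tidal targeting; no
alveolar gas correction).  For the standard protocol (110 → 430 mmHg
measured; 500 mmHg targeted) this gives ΔY_h = 0.066 and 0.077
respectively.

The per-vein fit φ_HO = a·φ_NO + k uses York's iterative
errors-in-both-coordinates solution: OLS initial slope, slope-dependent
weights W = w_x·w_y/(w_x + a²·w_y), convergence at |Δa| < 10⁻¹², 100
iterations maximum (non-convergence is flagged, not raised).  Slope SE
from the standard York variance.  Per-voxel phase errors are σ_φ =
1/SNR on both axes (first-order phase noise at magnitude SNR ≫ 1), one
global SNR per volume; the slope depends only on the x/y error ratio,
so a common mis-scaling of σ does not bias it.  No reference-tissue
phase is subtracted per vein: the intercept absorbs constant offsets,
which is the point of fitting slope and intercept separately.

Veins with fitted a ≥ 1 are flagged invalid (a non-physical
susceptibility increase on hyperoxia); veins with fewer than 10 voxels
(configurable) are skipped.  The subject-level summary is the mode of
the voxel-count-weighted Y_v histogram with bin width 0.02 on [0, 1]
(wide enough to avoid empty-bin noise at realistic vein counts; a KDE
mode is available).  The quoted uncertainty is the weighted SEM across
valid veins.  A linear-ramp fit to the inter-state phase difference
serves as a misregistration proxy and warns above 0.5 rad across the
FOV.

## Synthetic phantoms: what they emulate

The generator produces a paramagnetic vessel (analytic infinite-cylinder
field for straight geometry; the forward model for polyline tubes) in a
uniform background, with: polynomial background phase up to order 3
(optionally differing between gas states, to stress the filter), complex
Gaussian noise at magnitude SNR 20 (the phase SD in uniform regions then
equals 1/SNR, asserted), paired normoxia/hyperoxia volumes differing
exactly by the susceptibility ratio (1 − Y_v − ΔY_h)/(1 − Y_v), and
multi-echo magnitudes with Rician noise and R2* = 150 s⁻¹ in the vein vs
30 s⁻¹ outside (values chosen to straddle the 100 s⁻¹ threshold; the
multi-echo series is a separate acquisition and carries its own SNR,
default 50).  Defaults: 7 T, TE = 5 ms (multi-echo 5/10/15 ms), 0.65 mm
isotropic voxels, Hct = 0.4, Y_v = 0.62, ΔY_h = 0.066.  Phantom
parameters are constrained so |φ| < π everywhere; generation fails
loudly if a parameter choice would wrap.

What they do **not** emulate: brain anatomy and susceptibility
heterogeneity, flow effects, coil combination, partial-volume blur at
the vessel surface, vein-to-vein Y_v heterogeneity.  Passing the
round-trip tests therefore establishes internal consistency of the
estimators and the stated noise behaviour, not in-vivo accuracy.

## Monte Carlo design

Each replicate samples a fixed noiseless phase pattern — the
perpendicular-cylinder dipole pattern over the 200 voxels nearest the
vessel (a uniform-random-amplitude template is available for
sensitivity analysis) — scales it by the hyperoxia/normoxia ratio, adds
Gaussian phase noise σ = 1/SNR to both copies, York-fits and inverts.
Replicates with a ≥ 1 are counted and excluded.

The `template_yv` parameter separates two questions.  With the default
(template amplitude from `yv_true`) the simulation is a self-consistent
phantom.  With a fixed `template_yv` the template represents measured
data of given contrast while the hypothesised Y_v enters only through
the slope — the regime in which the negative skew of the Y_v
distribution (from the reciprocal 1/(1 − a)) grows as Y_v decreases;
with physical amplitude scaling the two effects cancel to first order
and the skew is nearly Y_v-independent.

## Problem sizes

Forward-model validation uses 128³ grids (padded to 256³) with vessel
aspect ratios ≥ 10; filter-bias comparisons use a radius-8 vessel on
128×128×64; end-to-end Method III uses 96×96×48 with a radius-2.5,
length-60 vein; the test-suite Monte Carlo uses 2000 replicates (the
API default is 10,000).  These sizes were chosen so the whole
verification chain runs in well under a minute each while keeping the
discretisation errors inside the stated tolerances.

## Known limitations

- No phase unwrapping: inputs with wrapped veins are the user's
  responsibility (a wrap warning fires when ROI phase approaches ±π).
- The homodyne-filter slope bias discussed above (~0.02 in Y_v at
  D = 64 for a 7 T, TE = 5 ms vein).
- Hct is assumed, and enters Y_v linearly through Δχ_IV.
- The Method III model assumes CBF/CBV/CMRO2 and oxygen extraction are
  unchanged by the isocapnic challenge, and that tissue susceptibility
  is unchanged by hyperoxia (the vein susceptibility change exceeds the
  tissue change by > 30×, recomputed by the acceptance script).
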