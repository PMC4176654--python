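# veinphase

Phase-based MR susceptometry of venous blood oxygenation (Y_v).

Deoxygenated haemoglobin is paramagnetic: a vein containing it perturbs
the static field B0, and the perturbation appears directly in the phase
of a gradient-echo image.  `veinphase` implements three estimators of
the venous oxygen saturation fraction Y_v from such phase data, for
researchers studying oxygen extraction (OEF ≈ 1 − Y_v) in health and in
conditions such as multiple sclerosis, traumatic brain injury or carotid
stenosis, and for calibrated-BOLD work that needs a measured rather than
assumed baseline Y_v.

## The model

The intravascular phase shift between a vein and adjacent tissue maps to
a field shift ΔB = Δφ_IV / (γ·TE), which relates to the vein–tissue
susceptibility difference Δχ_IV through a geometry factor *A*:
ΔB = A·B0·Δχ_IV.  With Δχ_IV = Hct·(1 − Y_v)·Δχ_do (Δχ_do = 3.32×10⁻⁶
SI, the susceptibility difference between fully deoxygenated and fully
oxygenated red cells),

    Y_v = 1 − Δφ_IV / (A · γ · TE · B0 · Hct · Δχ_do)

- **Method I** — infinite-cylinder approximation: A = (3cos²θ − 1)/6 for
  a straight vessel tilted at θ to B0 (A = 1/3 when parallel).
- **Method II** — forward field calculation: *A* is computed for the
  actual vessel shape by multiplying the binary vessel mask with the
  k-space dipole kernel 1/3 − k_z²/|k|², with the same Hanning k-space
  high-pass filter applied to the field map as to the phase data.  This
  removes the shape/orientation assumption and largely cancels the
  filter's bias.
- **Method III** — hyperoxia phase contrast: an isocapnic hyperoxia
  challenge raises Y_v by a known amount ΔY_h (computed from end-tidal
  O2 via the Severinghaus dissociation curve), scaling each vein's
  phase pattern.  Fitting φ_HO(r) = a·φ_NO(r) + k per vein with York
  errors-in-both-coordinates regression gives a = Δχ_HO/Δχ_NO and

      Y_v = 1 − ΔY_h / (1 − a),

  independent of vessel geometry and partial voluming, so Y_v can be
  mapped in small veins identified automatically from a multi-echo R2*
  map (threshold R2* > 100 s⁻¹).

A synthetic phantom module generates every input the pipeline consumes
(analytic or forward-model vessel fields, polynomial background phase,
complex noise at a stated SNR, paired normoxia/hyperoxia volumes,
multi-echo magnitudes), so the whole chain is verifiable without scanner
data.

## Worked example

Generate a noisy phantom with a small vein at Y_v = 0.66 and a hyperoxia
step of ΔY_h = 0.066, then run the Method III pipeline:

```python
import veinphase as vp
from veinphase.models import HyperoxiaPhaseContrast

spec = vp.PhantomSpec(shape=(96, 96, 48), radius=2.5, length=60, axis=(1, 0, 0),
                      yv_true=0.66, dyh_true=0.066, snr=20.0, seed=0,
                      background={(1, 0, 0): 0.4, (0, 2, 0): 0.3})
bundle = vp.make_pair(spec)
res = HyperoxiaPhaseContrast(
    bundle["complex_no"], bundle["complex_ho"], bundle["brain_mask"], spec.acq,
    blood=spec.blood,
    multi_echo=vp.MultiEchoSeries(bundle["magnitudes"], bundle["tes"]),
    snr=20.0, filter_d=64).fit()
print(res.summary())
```

```
Hyperoxia phase contrast (Method III)
==============================================
veins fitted            : 1
veins valid (a < 1)     : 1
dYh (gas model)         : 0.0660
Yv mode (voxel-weighted): 0.650
standard error          : 0.0080
```

The automatically segmented vein is fitted with slope a = 0.813
(truth 0.806); the D = 64 homodyne filter and SNR-20 noise leave the
recovered Y_v = 0.650 within 0.01 of the ground truth 0.66.  The
matching Monte Carlo (`vp.simulate_method3(yv_true=0.66, n_rep=10000,
seed=1)`) gives a distribution with median 0.660, SD 0.014 and a
negative skew (−0.30) from the reciprocal in the Y_v inversion.

The same objects drive Methods I/II
(`veinphase.models.IntravascularSusceptometry`), and a CLI exposes the
pipelines on NIfTI inputs:

```sh
veinphase simulate-phantom --spec spec.yaml --out bundle/
veinphase method1 --phase bundle/phase_no.nii.gz --sinus-mask bundle/vessel_mask.nii.gz \
    --brain-mask bundle/brain_mask.nii.gz --slices 12,14,16,18,20 --te 0.005 --out yv.json
veinphase montecarlo --n-rep 10000 --out-json mc.json
```

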