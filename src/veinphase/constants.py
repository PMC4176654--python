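"""Physical and physiological constants used throughout the package.

All susceptibilities are volume susceptibilities in SI (dimensionless);
cgs values differ by a factor of 4*pi.  Every value here is a default and
can be overridden through :class:`veinphase.params.AcquisitionParams` /
:class:`veinphase.params.BloodGasParams` or the CLI config file.
"""

import math

#: Proton gyromagnetic ratio, rad s^-1 T^-1 (CODATA).
GAMMA_PROTON = 2.6752218744e8

#: Volume susceptibility difference between fully deoxygenated and fully
#: oxygenated red blood cells, SI.
DCHI_DO_SI = 3.32e-6
#: Same quantity in cgs units (SI = 4*pi * cgs).
DCHI_DO_CGS = 0.264e-6

#: Susceptibility difference between fully oxygenated haemoglobin and
#: tissue (water), SI.  Negative: oxyhaemoglobin is slightly diamagnetic
#: relative to water.
DCHI_OXY_SI = -0.21e-6

#: cgs -> SI conversion for volume susceptibility.
SI_PER_CGS = 4.0 * math.pi

#: Default haematocrit fraction.
HCT_DEFAULT = 0.4

#: O2 carrying capacity of haemoglobin, ml(O2)/g.
PSI_O2 = 1.34
#: Haemoglobin concentration, g/dl(blood).
HB_DEFAULT = 15.0
#: Solubility of O2 in blood, ml/dl(blood)/mmHg.
EPSILON_O2 = 0.0031

#: R2* threshold for vein identification, s^-1.
R2S_VEIN_THRESHOLD = 100.0
#: Connected clusters with at least this many voxels are discarded
#: (rejects the inter-hemispheric fissure).
CLUSTER_MAX_VOXELS = 1200

#: Magic angle: cylinder tilt at which the intravascular field shift vanishes.
MAGIC_ANGLE = math.acos(1.0 / math.sqrt(3.0))
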