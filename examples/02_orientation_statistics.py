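"""Quantify orientation uniformity with axial circular statistics.

Orientation angles are axial (period 180 deg), so statistics are computed
on doubled angles.  The resultant vector length R is the uniformity index:
R = 1 for perfect alignment, R -> 0 for isotropy.  Five samples with
decreasing dispersion mimic tissue alignment improving with maturation.
"""

import numpy as np

from dichropam import OrientationSample, axial_resultant, summarize, sample_axial_vonmises

rng = np.random.default_rng(7)
print("dispersion(deg)   R      mean(deg)   95% CI")
for dispersion in (40.0, 30.0, 22.0, 15.0, 8.0):
    kappa = 1.0 / np.deg2rad(2.0 * dispersion) ** 2
    angles = sample_axial_vonmises(12.0, kappa, 4000, rng)
    summ = summarize(OrientationSample(angles), seed=1)
    lo, hi = summ.ci95_deg
    print(
        f"{dispersion:10.0f}   {summ.resultant_length:.3f}   {summ.mean_angle_deg:8.2f}"
        f"   [{lo:6.2f}, {hi:6.2f}]"
    )
# R rises monotonically as the angular dispersion falls, while the mean
# angle stays near the true 12 deg axis with a narrowing bootstrap CI.
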