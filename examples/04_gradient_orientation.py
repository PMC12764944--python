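"""Estimate fiber orientation from a grayscale image with the structure tensor.

The gradient-based comparator to dichroism mapping: derivative-of-Gaussian
gradients, a smoothed tensor, and per-pixel orientation of least intensity
variation with a coherence weight.
"""

import numpy as np

from dichropam import axial_resultant, field_to_sample, structure_tensor_orientation

yy, xx = np.mgrid[0:96, 0:96].astype(float)
angle = 30.0  # stripe axis
normal = np.deg2rad(angle + 90.0)
image = np.sin(2 * np.pi * (xx * np.cos(normal) + yy * np.sin(normal)) / 8.0)

field = structure_tensor_orientation(image, sigma_gradient=1.0, sigma_window=2.0)
sample = field_to_sample(field, coherence_min=0.5)
mean, r = axial_resultant(sample)
print(f"true stripe axis      : {angle:.2f} deg")
print(f"recovered mean axis   : {mean:.2f} deg")
print(f"resultant length R    : {r:.4f}")
print(f"pixels in sample      : {sample.n}")
# A single-orientation texture gives R ~ 1 and a mean within a fraction of
# a degree of the construction angle.
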