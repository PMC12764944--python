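"""Reconstruct amplitude maps from raw per-pixel time series.

Each scan position yields an A-line: a Gaussian-modulated ultrasound pulse
whose envelope peak encodes the local absorption.  The maximum-amplitude
projection (MAP) takes the per-pixel maximum of the analytic-signal
envelope, which is invariant to arrival time and carrier phase.
"""

import numpy as np

from dichropam import PhantomSpec, average_map, make_aline_volume, make_stack, stack_from_volumes

shape = (16, 16)
spec = PhantomSpec(
    orientation_field=np.full(shape, 30.0),
    iso_map=np.ones(shape),
    dichroic_map=np.ones(shape),
    seed=3,
)
volumes = make_aline_volume(spec, samples=256, depth_jitter=8e-9)
stack = stack_from_volumes(volumes)
reference, _ = make_stack(spec)

for angle in stack.angles:
    err = np.max(np.abs(stack[angle] - reference[angle]) / reference[angle])
    print(f"state {angle:5.0f} deg: MAP amplitude {stack[angle][0, 0]:.4f}, "
          f"max relative error {err:.2e}")
print(f"average map (a + b/2): {average_map(stack)[0, 0]:.4f}")
# The projected amplitudes match the Malus-model values (1.75, 1.933, 1.25,
# 1.067 for a=1, b=1, phi=30 deg) within 1% despite random pulse delays.
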