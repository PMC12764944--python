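"""Time action-potential activation from a voltage-dye movie.

A synthetic planar wave sweeps a tissue sheet at known speed, with a
"fibrotic" block that activates 40 ms late.  Fluorescence is normalized to
the resting baseline (F/F0) and each pixel's activation time is the
interpolated 50%-upstroke crossing.
"""

import numpy as np

from dichropam import activation_map, dff, make_wave_movie

speed = 600.0  # px/s
mask = np.zeros((8, 48), dtype=bool)
mask[:, 30:] = True
movie, truth = make_wave_movie(
    48, 8, speed_px_per_s=speed, fps=100.0, t0_ms=60.0,
    block_mask=mask, block_delay_ms=40.0,
)
act = activation_map(dff(movie))

row = np.nanmean(act.t_act[:, :30], axis=0)
x = np.arange(30)
sel = np.isfinite(row)
slope = np.polyfit(x[sel], row[sel], 1)[0]
print(f"true slope (1/speed)     : {1000.0 / speed:.3f} ms/px")
print(f"recovered slope          : {slope:.3f} ms/px")
unblocked_truth = truth - np.where(mask, 40.0, 0.0)
recovered_delay = np.nanmean((act.t_act - unblocked_truth)[mask])
print("injected block delay     : 40.0 ms")
print(f"recovered block delay    : {recovered_delay:.1f} ms")
# The t_act-vs-x slope recovers the inverse conduction speed to well within
# one frame period (10 ms), and the blocked region shows the injected delay.
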