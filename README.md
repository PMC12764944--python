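# dichropam

Analysis toolkit for **dichroism-sensitive photoacoustic microscopy
(DS-PAM)**: mapping the degree and orientation angle of linear dichroism
from polarization-resolved photoacoustic images, and quantifying how
uniformly a fibrous tissue is aligned.

Fibrous proteins (collagen, fibronectin, the extracellular matrix of
engineered heart tissue) absorb polarized mid-infrared light
anisotropically: absorption — and hence the photoacoustic amplitude —
peaks when the incident polarization aligns with the fiber axis.  From
four amplitude images `p_θ` acquired at incident polarization angles
θ ∈ {0°, 45°, 90°, 135°}, the linear Stokes parameters are

```
I = p0 + p90        Q = p0 − p90        U = p45 − p135
```

and per pixel

```
DoLD = sqrt(Q² + U²) / I        (degree of linear dichroism)
AoLD = ½ · atan2(U, Q)          (orientation angle, axial, [−90°, 90°))
```

For the Malus-law forward model `p_θ = a + b·cos²(θ − φ)` (isotropic
amplitude `a`, dichroic amplitude `b`, fiber axis `φ`) the inversion is
exact: `DoLD = b/(2a+b)` and `AoLD = φ`.  Orientation uniformity over a
region is the **resultant vector length** `R = |⟨exp(2iθ)⟩|` of the
doubled axial angles: 1 for perfect alignment, → 0 for isotropy.

The package covers the full analysis chain:

- `phantom` — synthetic fibrous phantoms with known ground truth
  (Malus-law stacks, pin-anchored orientation fields, A-line volumes,
  action-potential wave movies);
- `pa_recon` — analytic-signal envelope, maximum-amplitude projection,
  per-state fluence normalization, average map;
- `dichroism` — Stokes maps, DoLD/AoLD with validity flags, and an
  independent dense-angle least-squares cross-check;
- `orientation_stats` — axial mean angle, resultant length, bootstrap
  95% CIs, polar histograms, ROI summaries;
- `gradient_orientation` — structure-tensor fiber orientation from
  fluorescence-like images (the gradient-based comparator);
- `ap_mapping` — F/F₀ normalization, cycle extraction and per-pixel
  activation-time maps from voltage-dye movies;
- `io_formats` / `cli` — TIFF + JSON sidecar I/O and a thin `dichropam`
  command-line wrapper.

## Worked example

`examples/01_dichroism_mapping.py` builds a 64×80 phantom anchored on two
pins (circumferential orientation near the pins, longitudinal between
them), simulates the four polarization states with per-state fluence
drift and additive noise, removes the drift and inverts the Stokes
parameters:

```
mean DoLD            : 0.260
true DoLD            : 0.259
median |AoLD error|  : 1.19 deg
valid pixels         : 5120 / 5120
```

The mean DoLD matches the ground truth `b/(2a+b) = 0.7/2.7 ≈ 0.259` up to
noise, and the recovered orientation angle tracks the pin-anchored field
to about a degree per pixel.  `examples/02_orientation_statistics.py`
shows the maturation-style readout — resultant length rising from 0.25 to
0.96 as angular dispersion falls from 40° to 8° — and the remaining
examples demonstrate A-line reconstruction, the structure-tensor
comparator and activation-time mapping.  The same pipeline is scriptable:

```sh
dichropam run --config examples/demo_config.yaml --out demo_out/
```

which writes the simulated stack, DoLD/AoLD/mask/flag maps, an ROI
summary CSV, the AoLD histogram and a JSON run log, deterministically for
a fixed seed.

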