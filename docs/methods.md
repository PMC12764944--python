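# Methods

## Forward model and Stokes inversion

The package models polarization-resolved photoacoustic amplitudes of a
fibrous sample as an isotropic term plus a Malus-law dichroic term,

    p_θ(x, y) = g_θ · [ a(x, y) + b(x, y) · cos²(θ − φ(x, y)) ] + ε,

with `a ≥ 0` the isotropic absorption amplitude, `b ≥ 0` the dichroic
amplitude, `φ` the per-pixel fiber axis (axial, period 180°), `g_θ > 0` a
per-state laser-fluence drift factor and `ε` additive noise.  This is the
unique two-parameter linear-dichroism model that the four-angle Stokes
inversion reproduces exactly: expanding the cosine gives

    I = 2a + b,    Q = b·cos 2φ,    U = b·sin 2φ,

hence `DoLD = √(Q²+U²)/I = b/(2a+b)` and `AoLD = ½·atan2(U, Q) = φ`.
The inversion uses the quadrant-aware `atan2` rather than a plain
arctangent of U/Q: the latter cannot separate φ from φ+90° and is
undefined at Q = 0, while `atan2` recovers φ exactly on the forward model.
Angles are degrees, counter-clockwise from the image +x axis, reduced to
the canonical axial range [−90°, 90°) with the wrap at +90°.

Pixels are flagged rather than silently dropped: `LOW_SIGNAL` where
I falls below a threshold, `UNDEFINED_ANGLE` where Q = U = 0, and
`MODEL_INCONSISTENT` where DoLD > 1 (kept unclamped — a super-unity DoLD
is a diagnostic of noise or model violation, not a value to hide).  The
default threshold is 5× a robust noise scale of I, estimated from the
normalized median absolute deviation of the below-median tail of the I
map so that foreground structure does not inflate it; it is overridable,
and all exact-inversion tests pass `min_signal=0` explicitly.

An independent per-pixel least-squares fit of
`p_θ = c0 + c1·cos 2θ + c2·sin 2θ` over K ≥ 3 angles spanning ≥ 90°
(`dense_fit_oracle`) serves as the cross-check of the four-angle
inversion and generalizes it to arbitrary angle sets; the two agree to
machine precision on noiseless canonical stacks.  The Stokes path itself
requires exactly the four canonical states, since the Q and U differences
are defined only for them.

## Reconstruction

A-lines are reduced to amplitudes by the magnitude of the analytic signal
(Hilbert transform), which is invariant to carrier phase, sign and
arrival time; the maximum-amplitude projection takes the per-pixel
envelope maximum over time.  Fluence normalization divides each state's
image by that state's recorded fluence — a scalar per polarization state,
matching per-pulse power monitoring — and only fluence *ratios* matter.
The "average map" is the arithmetic mean over the four states, which for
the Malus model equals `a + b/2 = I/2`; the mean over all four
measurements is preferred over `I/2` because it uses every acquisition
(the two agree under the model).  An optional zero-phase Butterworth
bandpass is available before projection but is off by default.

## Axial circular statistics

Orientations are undirected, so every statistic is computed on the
doubled angles `2θ` and mapped back by halving.  The resultant vector
length `R = |Σ w·exp(2iθ)/Σ w|` is the uniformity index; the axial mean
is half the argument of the same complex mean; the circular SD on the
axial scale is `√(−2 ln R)/2`.  The 95% CI of the mean angle defaults to
a seeded percentile bootstrap (n_boot = 1000) of the doubled-angle mean,
with bootstrap deviations centered on the point estimate to avoid wrap
artifacts at ±90°; a large-sample alternative ("fisher") uses the
circular standard error from the second trigonometric moment.  Measured
coverage at concentration κ = 4, n = 200 is ~95% for both.  ROI summaries
optionally weight the axial statistics by amplitude or by DoLD;
unweighted over valid pixels is the default.  Histograms default to 18
bins of 10° over [−90°, 90°).

Axial von Mises samples (doubled angles ~ von Mises(2μ, κ)) are the test
distribution; their expected doubled-angle resultant is the Bessel ratio
I₁(κ)/I₀(κ), which the estimator reproduces within sampling error.

## Synthetic phantoms

The generator emits, alongside every stack, the exact ground truth
(orientation field, `b/(2a+b)` map, foreground mask).  Noise is additive
Gaussian clipped at zero — amplitudes are envelope maxima and cannot be
negative — with a Rician option for envelope-like statistics; the noise
law of real acquisitions is not modeled beyond this.  Defaults used by
the examples and checks: unit isotropic amplitude, dichroic amplitude
0.7–0.8 (DoLD ≈ 0.26–0.29, the same order as measured fibrous threads),
noise σ = 0.05 (SNR ≈ 20 on I), fluence drift factors within ±8%.

The pin-anchored orientation field emulates tissue grown on an anchoring
platform: circumferential alignment around each pin, relaxing to the
longitudinal tension axis between pins.  It is the tangent field of the
level sets of a potential `Σ_i exp(−d_i/blend_length)` over pins `i`: one
pin gives exact circles, and between two pins the opposing gradients
cancel so the tangent aligns with the pin axis; pixels where the gradient
is numerically zero fall back to the pin-axis direction.  `blend_length`
(default 20 px) sets how far each pin's circumferential influence
reaches.

A-line volumes place a Gaussian-modulated sinusoid
(`scipy.signal.gausspulse`, 30 MHz center, 60% fractional bandwidth,
250 MHz sampling) at a per-pixel random delay with the pixel amplitude as
envelope peak.  Wave movies advance a logistic upstroke (10–90% rise
time 20 ms) along +x at a set speed, 100 frames/s by default, with an
optional "fibrotic" block that activates late and/or with reduced
amplitude.

What passing tests on these phantoms show — and what they do not: the
inversion, statistics and timing pipelines are exact or well-calibrated
under the stated forward models; real tissue adds spatially correlated
speckle, depth-dependent fluence, partial-volume mixing of fiber
populations and acoustic effects that the phantoms deliberately omit (no
wave propagation, transducer response or diffraction is modeled; optics
enter only as an optional Gaussian blur).

## Gradient comparator

The fluorescence-side orientation estimator uses the structure tensor
(derivative-of-Gaussian gradients, σ_gradient = 1 px; tensor smoothing,
σ_window = 2 px) rather than raw per-pixel gradient angles: it estimates
the same quantity but degrades gracefully in noise.  Orientation is the
axis of least intensity variation (perpendicular to the dominant
gradient); coherence `(λ₁−λ₂)/(λ₁+λ₂)` weights pixels when pooling into a
sample.  Pixels with zero tensor energy and a border of 3·σ_window are
invalid.  A constant image therefore yields an empty sample, signalled by
`EmptySampleError` rather than a crash.

## Activation mapping

F/F₀ uses a per-pixel 10th-percentile baseline by default (robust when
the rest period is short; `first_k` mean is the alternative).  The cycle
window backs up from the first half-max crossing of the smoothed
spatial-mean trace to the upstroke onset (10% of range) so the window
contains the full wave transit, ending at the next cycle's onset, at
recovery, or at the end of the recording.  Activation time defaults to
the linearly interpolated 50%-upstroke crossing of each pixel's own
amplitude; `dvdt` (parabolic-refined maximum derivative, 3-frame moving
average) is the alternative, and the two agree within one frame period on
noiseless sigmoidal upstrokes.  Pixels with upstroke amplitude below a
noise floor (default 0.02 in F/F₀ units) are NaN.

## Problem sizes and determinism

The bundled checks use 64×64–96×96 images, 10⁴–10⁵-angle samples, 500
bootstrap-coverage replicates and 48-column wave movies — sizes at which
every calibration quantity is stable to well within its tolerance.  All
randomness flows through `numpy.random.default_rng` seeds carried in
specs and function arguments; the demo pipeline is byte-reproducible, and
every figure-like output has a numeric sidecar (CSV/JSON) carrying the
exact plotted values.

## Known limitations

Only the four canonical polarization states feed the Stokes path; there
is no circular dichroism, Mueller-matrix polarimetry or birefringence
(phase-retardation) estimation.  No depth-resolved analysis, conduction
velocity vector fields, motion correction or group hypothesis testing.
The TIFF + sidecar format is this package's own contract, not an
instrument format.
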