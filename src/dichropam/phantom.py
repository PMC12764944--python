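"""Synthetic fibrous phantoms with known ground truth.

The forward model for polarization-resolved photoacoustic amplitudes is an
isotropic absorption term plus a Malus-law dichroic term,

    p_theta(x, y) = g_theta * [ a(x, y) + b(x, y) * cos^2(theta - phi(x, y)) ] + noise,

where ``a`` is the isotropic amplitude, ``b`` the dichroic amplitude,
``phi`` the per-pixel fiber axis and ``g_theta`` a per-state fluence drift
factor.  This is the unique two-parameter linear-dichroism model that the
four-angle Stokes inversion recovers exactly: the true degree of linear
dichroism is b / (2a + b) and the true orientation angle is phi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import gausspulse

from .core import (
    CANONICAL_ANGLES,
    ALineVolume,
    PolarizationStack,
    StackMetadata,
    VoltageMovie,
    wrap_axial,
)

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "make_stack",
    "make_pin_field",
    "make_aline_volume",
    "make_wave_movie",
]


@dataclass
class PhantomSpec:
    """Ground-truth description of a synthetic dichroic sample.

    Per-pixel maps must share one shape.  ``orientation_field`` is in
    degrees and is reduced into [-90, 90) on construction;
    ``fluence_factors`` is one multiplicative drift factor per incident
    polarization state.
    """

    orientation_field: np.ndarray
    iso_map: np.ndarray
    dichroic_map: np.ndarray
    noise_sigma: float = 0.0
    fluence_factors: dict[float, float] | None = None
    seed: int = 0
    angles: tuple[float, ...] = CANONICAL_ANGLES
    noise_model: str = "gaussian"  # or "rician"

    def __post_init__(self) -> None:
        self.orientation_field = wrap_axial(np.asarray(self.orientation_field, float))
        self.iso_map = np.asarray(self.iso_map, dtype=float)
        self.dichroic_map = np.asarray(self.dichroic_map, dtype=float)
        shapes = {
            self.orientation_field.shape,
            self.iso_map.shape,
            self.dichroic_map.shape,
        }
        if len(shapes) != 1:
            raise ValueError(f"phantom maps have mismatched shapes: {shapes}")
        if np.any(self.iso_map < 0) or np.any(self.dichroic_map < 0):
            raise ValueError("absorption maps must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.fluence_factors is None:
            self.fluence_factors = {float(a): 1.0 for a in self.angles}
        if any(g <= 0 for g in self.fluence_factors.values()):
            raise ValueError("fluence factors must be positive")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")

    @property
    def shape(self) -> tuple[int, int]:
        return self.iso_map.shape

    def clean_amplitude(self, angle_deg: float) -> np.ndarray:
        """Noise-free, drift-free Malus amplitude a + b cos^2(theta - phi)."""
        delta = np.deg2rad(angle_deg - self.orientation_field)
        return self.iso_map + self.dichroic_map * np.cos(delta) ** 2


@dataclass
class PhantomTruth:
    """Ground truth emitted with every synthetic stack, for validation."""

    orientation_field: np.ndarray
    dold_true: np.ndarray
    foreground_mask: np.ndarray


def make_stack(spec: PhantomSpec) -> tuple[PolarizationStack, PhantomTruth]:
    """Generate a polarization-resolved amplitude stack plus its ground truth.

    Each state's image is the Malus amplitude scaled by that state's
    fluence drift, with additive noise, clipped at zero (amplitudes are
    envelope maxima and cannot be negative).  Bit-reproducible for a
    fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    images: dict[float, np.ndarray] = {}
    for angle in spec.angles:
        clean = spec.fluence_factors[float(angle)] * spec.clean_amplitude(angle)
        if spec.noise_sigma > 0:
            if spec.noise_model == "rician":
                nr = rng.normal(0.0, spec.noise_sigma, spec.shape)
                ni = rng.normal(0.0, spec.noise_sigma, spec.shape)
                img = np.hypot(clean + nr, ni)
            else:
                img = clean + rng.normal(0.0, spec.noise_sigma, spec.shape)
        else:
            img = clean
        images[float(angle)] = np.clip(img, 0.0, None)

    meta = StackMetadata(
        angles_deg=[float(a) for a in spec.angles],
        fluence=[spec.fluence_factors[float(a)] for a in spec.angles],
        provenance="synthetic Malus-law phantom",
    )
    stack = PolarizationStack(images, meta)

    total = 2.0 * spec.iso_map + spec.dichroic_map
    with np.errstate(invalid="ignore", divide="ignore"):
        dold_true = np.where(total > 0, spec.dichroic_map / total, np.nan)
    truth = PhantomTruth(
        orientation_field=spec.orientation_field.copy(),
        dold_true=dold_true,
        foreground_mask=(spec.iso_map + spec.dichroic_map) > 0,
    )
    return stack, truth


def make_pin_field(
    width: int,
    height: int,
    pin_positions: list[tuple[float, float]],
    blend_length: float = 20.0,
) -> np.ndarray:
    """Orientation field emulating tissue anchored on pins.

    Near each pin the field is circumferential (tangent to circles around
    the pin, mimicking the mechanical constraint of an anchoring post);
    away from the pins it relaxes toward the longitudinal tension axis.
    The field is the tangent direction of the level sets of a potential
    ``sum_i exp(-d_i / blend_length)``: a single pin gives exact circles,
    while between two pins the contributions cancel on the pin axis and
    the tangent aligns with the axis.  Larger ``blend_length`` extends the
    longitudinal region between the pins.

    Parameters are in pixels; ``pin_positions`` are (x, y) pairs that must
    lie inside the ``width`` x ``height`` canvas.  Returns angles in
    degrees in [-90, 90).
    """
    if not pin_positions:
        raise ValueError("at least one pin position is required")
    for px, py in pin_positions:
        if not (0 <= px < width and 0 <= py < height):
            raise ValueError(f"pin ({px}, {py}) lies outside the canvas")
    if blend_length <= 0:
        raise ValueError("blend_length must be positive")

    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    # gradient of the potential; orientation is perpendicular to it
    gx = np.zeros((height, width))
    gy = np.zeros((height, width))
    for px, py in pin_positions:
        dx, dy = xx - px, yy - py
        d = np.hypot(dx, dy)
        d = np.where(d == 0, 1e-12, d)
        w = np.exp(-d / blend_length) / d
        gx += w * dx
        gy += w * dy

    if len(pin_positions) >= 2:
        (x0, y0), (x1, y1) = pin_positions[0], pin_positions[-1]
        longitudinal = np.degrees(np.arctan2(y1 - y0, x1 - x0))
    else:
        longitudinal = 0.0

    mag = np.hypot(gx, gy)
    tangent = np.degrees(np.arctan2(gy, gx)) + 90.0
    floor = 1e-9 * max(mag.max(), 1e-300)
    theta = np.where(mag > floor, tangent, longitudinal)
    return wrap_axial(theta)


def make_aline_volume(
    spec: PhantomSpec,
    pulse_center_freq: float = 30e6,
    pulse_bandwidth: float = 0.6,
    samples: int = 256,
    sample_rate: float = 250e6,
    depth_jitter: float = 0.0,
) -> dict[float, ALineVolume]:
    """Synthesize per-state A-line volumes whose envelope peaks are the stack amplitudes.

    Each pixel's time series is a Gaussian-modulated sinusoid (center
    frequency and fractional bandwidth as in ``scipy.signal.gausspulse``)
    whose envelope maximum equals the pixel's noisy Malus amplitude, at a
    per-pixel random arrival time.  ``depth_jitter`` is the standard
    deviation of that arrival time in seconds.  Returns one volume per
    polarization state, keyed by angle.
    """
    if sample_rate <= 2 * pulse_center_freq:
        raise ValueError("sample_rate must exceed twice the pulse center frequency")
    stack, _ = make_stack(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x41]))
    ny, nx = spec.shape
    t = np.arange(samples) / sample_rate
    t0 = t[samples // 2]

    volumes: dict[float, ALineVolume] = {}
    for angle in stack.angles:
        amp = stack[angle]
        delays = t0 + (
            rng.normal(0.0, depth_jitter, (ny, nx)) if depth_jitter > 0 else 0.0
        )
        # (ny, nx, nt) pulse bank; gausspulse has unit envelope peak at t=0
        tt = t[None, None, :] - np.atleast_2d(delays)[..., None] * np.ones((ny, nx, 1))
        pulses = gausspulse(tt, fc=pulse_center_freq, bw=pulse_bandwidth)
        volumes[angle] = ALineVolume(
            signals=amp[..., None] * pulses,
            sample_rate=sample_rate,
            angle_deg=angle,
        )
    return volumes


def make_wave_movie(
    width: int,
    height: int,
    speed_px_per_s: float,
    fps: float = 100.0,
    n_frames: int | None = None,
    upstroke_ms: float = 20.0,
    amplitude: float = 1.0,
    baseline: float = 1.0,
    block_mask: np.ndarray | None = None,
    block_delay_ms: float = 0.0,
    block_amplitude_scale: float = 1.0,
    t0_ms: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[VoltageMovie, np.ndarray]:
    """Planar action-potential wave movie with known activation times.

    A fluorescence upstroke travels along +x: the column at ``x`` activates
    at ``t = x / speed_px_per_s``.  Pixels inside ``block_mask`` (a fibrotic
    surrogate) activate ``block_delay_ms`` later with their upstroke
    amplitude scaled by ``block_amplitude_scale``.  The upstroke is a
    logistic sigmoid with 10-90% rise time ``upstroke_ms``.

    Returns the movie and the ground-truth activation-time map in ms.
    """
    if speed_px_per_s <= 0 or fps <= 0 or amplitude < 0:
        raise ValueError("speed and fps must be positive, amplitude non-negative")
    transit_ms = t0_ms + 1000.0 * (width - 1) / speed_px_per_s + block_delay_ms
    if n_frames is None:
        n_frames = int(np.ceil((transit_ms + 4 * upstroke_ms) * fps / 1000.0)) + 5
    if (n_frames - 1) * 1000.0 / fps < transit_ms:
        raise ValueError("n_frames too small to contain the wave transit")

    xx = np.arange(width, dtype=float)
    t_act = np.tile(t0_ms + 1000.0 * xx / speed_px_per_s, (height, 1))
    amp_map = np.full((height, width), amplitude)
    if block_mask is not None:
        block_mask = np.asarray(block_mask, dtype=bool)
        t_act = t_act + np.where(block_mask, block_delay_ms, 0.0)
        amp_map = np.where(block_mask, amplitude * block_amplitude_scale, amp_map)

    times = np.arange(n_frames) * 1000.0 / fps
    # logistic with 10-90% rise = upstroke_ms  =>  tau = upstroke_ms / (2 ln 9)
    tau = upstroke_ms / (2.0 * np.log(9.0))
    arg = (times[:, None, None] - t_act[None, :, :]) / tau
    frames = baseline + amp_map[None, :, :] / (1.0 + np.exp(-np.clip(arg, -500, 500)))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, noise_sigma, frames.shape)
    movie = VoltageMovie(frames=frames, fps=fps)
    return movie, t_act
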