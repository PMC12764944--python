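"""A-line reconstruction: envelope detection, maximum-amplitude projection,
fluence normalization and the average map.

The per-pixel time series is reduced to a single amplitude by taking the
maximum of the analytic-signal envelope, which is phase- and sign-invariant
and insensitive to arrival-time shifts.  Per-state images are then divided
by the laser fluence recorded for that polarization state, so that only the
sample's polarization response — not source drift — enters the Stokes maps.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .core import ALineVolume, PolarizationStack, StackMetadata

__all__ = ["envelope", "map_project", "fluence_normalize", "average_map", "MAPImage"]


from dataclasses import dataclass


@dataclass
class MAPImage:
    """Maximum-amplitude-projection image for one polarization state."""

    amplitude: np.ndarray
    angle_deg: float

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if np.any(self.amplitude < 0):
            raise ValueError("MAP amplitudes must be non-negative")


def envelope(aline: np.ndarray, axis: int = -1) -> np.ndarray:
    """Magnitude of the analytic signal along ``axis``.

    Length-preserving and non-negative; for a modulated carrier it tracks
    the modulation envelope independent of carrier phase.
    """
    aline = np.asarray(aline, dtype=float)
    if aline.shape[axis] < 8:
        raise ValueError("need at least 8 samples for envelope estimation")
    if np.isnan(aline).all():
        raise ValueError("all-NaN A-line")
    return np.abs(hilbert(aline, axis=axis))


def bandpass(
    volume: ALineVolume, low_hz: float, high_hz: float, order: int = 4
) -> ALineVolume:
    """Optional zero-phase Butterworth pre-filter before projection."""
    nyq = volume.sample_rate / 2.0
    sos = butter(order, [low_hz / nyq, high_hz / nyq], btype="band", output="sos")
    return ALineVolume(
        signals=sosfiltfilt(sos, volume.signals, axis=-1),
        sample_rate=volume.sample_rate,
        angle_deg=volume.angle_deg,
    )


def map_project(volume: ALineVolume) -> MAPImage:
    """Per-pixel maximum of the A-line envelope over time."""
    if volume.signals.shape[-1] == 0:
        raise ValueError("empty time axis")
    env = envelope(volume.signals, axis=-1)
    return MAPImage(amplitude=env.max(axis=-1), angle_deg=volume.angle_deg)


def stack_from_volumes(
    volumes: dict[float, ALineVolume], meta: StackMetadata | None = None
) -> PolarizationStack:
    """Project each state's volume and assemble a polarization stack."""
    images = {a: map_project(v).amplitude for a, v in volumes.items()}
    if meta is None:
        meta = StackMetadata(
            angles_deg=sorted(images), fluence=[1.0] * len(images)
        )
    return PolarizationStack(images, meta)


def fluence_normalize(stack: PolarizationStack, meta: StackMetadata | None = None) -> PolarizationStack:
    """Divide each state's image pixel-by-pixel by that state's laser fluence.

    Scale-invariant by design: multiplying one state's raw image and its
    fluence record by the same constant leaves the output unchanged.
    """
    meta = meta or stack.meta
    if any(meta.fluence_for(a) <= 0 for a in stack.angles):
        raise ValueError("fluence must be positive for every state")
    normalized = stack.map(lambda a, img: img / meta.fluence_for(a))
    normalized.meta = StackMetadata(
        angles_deg=list(meta.angles_deg),
        fluence=[1.0] * len(meta.angles_deg),
        pixel_size_um=meta.pixel_size_um,
        provenance=meta.provenance,
    )
    return normalized


def average_map(stack: PolarizationStack) -> np.ndarray:
    """Arithmetic mean of the per-state images: the polarization-averaged map.

    For the Malus model with canonical angles this equals a + b/2 pixelwise,
    i.e. half of the Stokes I parameter.
    """
    if not stack.images:
        raise ValueError("empty stack")
    return np.mean([stack[a] for a in stack.angles], axis=0)
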