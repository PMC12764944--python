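"""Shared containers and angle conventions.

Angles are measured in degrees, counter-clockwise from the image +x axis
(columns).  Orientations are *axial* quantities: an angle and the same
angle plus 180 deg describe the same fiber axis, so every orientation is
reduced modulo 180 into the canonical half-open range [-90, 90).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The four incident polarization states of the Stokes scheme, degrees.
CANONICAL_ANGLES: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)


def wrap_axial(angles_deg):
    """Reduce angles modulo 180 into the canonical range [-90, 90)."""
    a = np.asarray(angles_deg, dtype=float)
    return (a + 90.0) % 180.0 - 90.0


def canonical_angle(angle_deg: float) -> float:
    """Reduce a single incident-polarization angle to its axial equivalent in [0, 180)."""
    return float(np.asarray(angle_deg, dtype=float) % 180.0)


@dataclass
class StackMetadata:
    """Acquisition metadata for a polarization-resolved stack.

    Parameters
    ----------
    angles_deg
        Incident polarization angles, unique modulo 180.
    fluence
        Per-state laser fluence in arbitrary units (> 0).  Only ratios
        between states matter: fluence normalization is scale invariant.
    pixel_size_um
        Physical pixel pitch in micrometers.
    provenance
        Free-text note on where the stack came from.
    """

    angles_deg: list[float]
    fluence: list[float]
    pixel_size_um: float = 1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        canon = [canonical_angle(a) for a in self.angles_deg]
        if len(set(canon)) != len(canon):
            raise ValueError("polarization angles must be unique modulo 180")
        if len(self.fluence) != len(self.angles_deg):
            raise ValueError("fluence length must equal the number of angles")
        if any(f <= 0 for f in self.fluence):
            raise ValueError("fluence values must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        self.angles_deg = canon

    def fluence_for(self, angle_deg: float) -> float:
        return self.fluence[self.angles_deg.index(canonical_angle(angle_deg))]


@dataclass
class PolarizationStack:
    """Co-registered amplitude images keyed by incident polarization angle."""

    images: dict[float, np.ndarray]
    meta: StackMetadata

    def __post_init__(self) -> None:
        canon: dict[float, np.ndarray] = {}
        for angle, img in self.images.items():
            a = canonical_angle(angle)
            if a in canon:
                raise ValueError(f"duplicate polarization angle {angle} (axially {a})")
            canon[a] = np.asarray(img, dtype=float)
        shapes = {img.shape for img in canon.values()}
        if len(shapes) > 1:
            raise ValueError(f"polarization pages have mismatched shapes: {shapes}")
        self.images = canon

    @property
    def angles(self) -> list[float]:
        return sorted(self.images)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.images.values())).shape

    def __getitem__(self, angle_deg: float) -> np.ndarray:
        return self.images[canonical_angle(angle_deg)]

    def map(self, fn) -> "PolarizationStack":
        """Apply ``fn(angle, image) -> image`` to every state."""
        return PolarizationStack(
            {a: fn(a, img) for a, img in self.images.items()}, self.meta
        )


@dataclass
class ALineVolume:
    """Per-pixel photoacoustic time series for one polarization state.

    ``signals`` has shape (ny, nx, nt); ``sample_rate`` is in Hz.
    """

    signals: np.ndarray
    sample_rate: float
    angle_deg: float

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 3:
            raise ValueError("A-line volume must be 3-D (ny, nx, nt)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("A-line volume contains non-finite samples")


@dataclass
class VoltageMovie:
    """Voltage-dye fluorescence movie: frames (nt, ny, nx) at ``fps`` Hz."""

    frames: np.ndarray
    fps: float
    roi_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("movie must be (nt, ny, nx) with at least 2 frames")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.roi_mask is not None:
            self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
            if self.roi_mask.shape != self.frames.shape[1:]:
                raise ValueError("roi_mask shape must match the frame shape")

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.frames.shape[0]) * 1000.0 / self.fps
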