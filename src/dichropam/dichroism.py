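"""Stokes-parameter mapping of linear dichroism.

From four fluence-normalized amplitude images at incident polarization
angles 0, 45, 90 and 135 degrees the linear Stokes parameters are

    I = p0 + p90,    Q = p0 - p90,    U = p45 - p135,

and per pixel

    DoLD = sqrt(Q^2 + U^2) / I          (degree of linear dichroism)
    AoLD = (1/2) * atan2(U, Q)          (orientation angle, degrees)

DoLD is 0 for isotropic absorption and b/(2a+b) for the Malus model
p_theta = a + b cos^2(theta - phi); AoLD recovers phi exactly.  The
quadrant-aware atan2 is used so that the orientation is resolved over the
full axial period; the result is wrapped into [-90, 90).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .core import CANONICAL_ANGLES, PolarizationStack, wrap_axial

__all__ = [
    "Flag",
    "StokesMaps",
    "DichroismResult",
    "stokes_maps",
    "dold_map",
    "aold_map",
    "compute_dichroism",
    "dense_fit_oracle",
    "auto_min_signal",
]


class Flag(IntEnum):
    """Per-pixel validity code."""

    OK = 0
    LOW_SIGNAL = 1
    UNDEFINED_ANGLE = 2
    MODEL_INCONSISTENT = 3


@dataclass
class StokesMaps:
    I: np.ndarray
    Q: np.ndarray
    U: np.ndarray

    def __post_init__(self) -> None:
        if not (self.I.shape == self.Q.shape == self.U.shape):
            raise ValueError("Stokes maps must share one shape")


@dataclass
class DichroismResult:
    """Per-pixel DoLD/AoLD maps with a validity mask and diagnostic flags."""

    dold: np.ndarray
    aold_deg: np.ndarray
    valid_mask: np.ndarray
    flags: np.ndarray


def stokes_maps(stack: PolarizationStack) -> StokesMaps:
    """Stokes parameter maps from the four canonical polarization states.

    The stack must contain exactly the angles {0, 45, 90, 135} (after
    axial reduction); other angle sets require :func:`dense_fit_oracle`.
    """
    angles = set(stack.angles)
    if angles != set(CANONICAL_ANGLES):
        raise ValueError(
            f"Stokes mapping needs exactly the states {sorted(CANONICAL_ANGLES)}, "
            f"got {sorted(angles)}"
        )
    p0, p45, p90, p135 = (stack[a] for a in CANONICAL_ANGLES)
    return StokesMaps(I=p0 + p90, Q=p0 - p90, U=p45 - p135)


def auto_min_signal(s: StokesMaps, k: float = 5.0) -> float:
    """Robust signal threshold: ``k`` times the MAD-based noise scale of I.

    The scale is the normalized median absolute deviation of the I map's
    below-median tail, which tracks the background noise floor even when
    foreground structure dominates the image.
    """
    i = s.I[np.isfinite(s.I)]
    background = i[i <= np.median(i)]
    sigma = 1.4826 * np.median(np.abs(background - np.median(background)))
    return float(k * sigma)


def dold_map(
    s: StokesMaps, min_signal: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Degree of linear dichroism, sqrt(Q^2 + U^2) / I, with flags.

    Pixels with I below ``min_signal`` are flagged LOW_SIGNAL (NaN in the
    map); DoLD > 1 signals a model violation and is flagged
    MODEL_INCONSISTENT but the value is retained, not clamped — it is a
    useful noise diagnostic.
    """
    if min_signal is None:
        min_signal = auto_min_signal(s)
    if min_signal < 0:
        raise ValueError("min_signal must be non-negative")
    flags = np.full(s.I.shape, Flag.OK, dtype=np.uint8)
    ok = s.I >= np.maximum(min_signal, np.finfo(float).tiny)
    with np.errstate(invalid="ignore", divide="ignore"):
        dold = np.where(ok, np.hypot(s.Q, s.U) / np.where(ok, s.I, 1.0), np.nan)
    flags[~ok] = Flag.LOW_SIGNAL
    flags[ok & (dold > 1.0)] = Flag.MODEL_INCONSISTENT
    return dold, flags


def aold_map(
    s: StokesMaps, min_signal: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Orientation angle of linear dichroism, (1/2) atan2(U, Q), in degrees.

    Wrapped into [-90, 90).  Pixels with Q = U = 0 have no defined
    orientation (UNDEFINED_ANGLE, NaN); pixels below ``min_signal`` are
    LOW_SIGNAL.
    """
    if min_signal is None:
        min_signal = auto_min_signal(s)
    flags = np.full(s.I.shape, Flag.OK, dtype=np.uint8)
    aold = wrap_axial(np.degrees(0.5 * np.arctan2(s.U, s.Q)))
    undefined = (s.Q == 0) & (s.U == 0)
    aold = np.where(undefined, np.nan, aold)
    flags[undefined] = Flag.UNDEFINED_ANGLE
    low = s.I < min_signal
    aold = np.where(low, np.nan, aold)
    flags[low] = Flag.LOW_SIGNAL
    return aold, flags


def compute_dichroism(
    stack: PolarizationStack, min_signal: float | None = None
) -> DichroismResult:
    """Full DoLD/AoLD mapping with a combined validity mask."""
    s = stokes_maps(stack)
    if min_signal is None:
        min_signal = auto_min_signal(s)
    dold, dflags = dold_map(s, min_signal)
    aold, aflags = aold_map(s, min_signal)
    flags = np.maximum(dflags, aflags)
    valid = flags == Flag.OK
    return DichroismResult(dold=dold, aold_deg=aold, valid_mask=valid, flags=flags)


def dense_fit_oracle(
    images: dict[float, np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Independent least-squares estimator of the Malus model parameters.

    Fits p_theta = c0 + c1 cos(2 theta) + c2 sin(2 theta) per pixel over
    K >= 3 distinct angles spanning at least 90 degrees, and returns maps
    (a_hat, b_hat, phi_hat) with b_hat = 2 sqrt(c1^2 + c2^2),
    a_hat = c0 - b_hat / 2 and phi_hat = (1/2) atan2(c2, c1) in degrees.
    On noiseless canonical four-angle input this agrees exactly with the
    Stokes inversion; it serves as its cross-check and extends the
    inversion to arbitrary angle sets.  Pixels with b_hat = 0 get
    phi_hat = NaN (orientation undefined).
    """
    angles = np.array(sorted(images), dtype=float)
    if len(angles) < 3:
        raise ValueError("need at least 3 distinct angles")
    rad2 = np.deg2rad(2.0 * angles)
    design = np.column_stack([np.ones_like(rad2), np.cos(rad2), np.sin(rad2)])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("angles are collinear modulo 180 degrees (rank-deficient fit)")
    shape = images[angles[0]].shape
    y = np.stack([np.asarray(images[a], float).ravel() for a in angles])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    c0, c1, c2 = (c.reshape(shape) for c in coef)
    b_hat = 2.0 * np.hypot(c1, c2)
    a_hat = c0 - b_hat / 2.0
    # orientation is undefined when the dichroic term is numerically zero
    defined = b_hat > 1e-10 * np.maximum(np.abs(c0), 1.0)
    phi_hat = np.where(
        defined, wrap_axial(np.degrees(0.5 * np.arctan2(c2, c1))), np.nan
    )
    return a_hat, b_hat, phi_hat
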