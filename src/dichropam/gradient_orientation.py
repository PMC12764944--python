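"""Structure-tensor orientation estimation for fluorescence-like images.

The comparator to dichroism mapping: local fiber orientation inferred from
intensity gradients alone.  Gradients are taken with derivative-of-Gaussian
filters, their outer products smoothed over a Gaussian window, and the
orientation of least intensity variation (perpendicular to the dominant
gradient) extracted per pixel together with a coherence weight
(lambda1 - lambda2) / (lambda1 + lambda2) in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import wrap_axial
from .orientation_stats import EmptySampleError, OrientationSample

__all__ = ["OrientationFieldImage", "structure_tensor_orientation", "field_to_sample"]


@dataclass
class OrientationFieldImage:
    """Per-pixel axial orientation (degrees, [-90, 90)), coherence and validity."""

    theta_deg: np.ndarray
    coherence: np.ndarray
    valid: np.ndarray


def structure_tensor_orientation(
    image: np.ndarray, sigma_gradient: float = 1.0, sigma_window: float = 2.0
) -> OrientationFieldImage:
    """Per-pixel orientation of image structure via the structure tensor.

    ``sigma_gradient`` sets the derivative-of-Gaussian scale and
    ``sigma_window`` the tensor-averaging window (both in pixels).  The
    returned orientation is the axis along which intensity varies least —
    the fiber axis for line-like structures.  Pixels with zero tensor
    energy and a border of width 3 * sigma_window (filter support) are
    marked invalid.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if sigma_gradient <= 0 or sigma_window <= 0:
        raise ValueError("sigmas must be positive")

    # derivative-of-Gaussian gradients; axis 0 = rows (y), axis 1 = cols (x)
    gy = gaussian_filter(image, sigma_gradient, order=(1, 0))
    gx = gaussian_filter(image, sigma_gradient, order=(0, 1))
    jxx = gaussian_filter(gx * gx, sigma_window)
    jxy = gaussian_filter(gx * gy, sigma_window)
    jyy = gaussian_filter(gy * gy, sigma_window)

    trace = jxx + jyy
    # dominant-gradient orientation is 0.5*atan2(2Jxy, Jxx-Jyy); structure is +90
    theta = wrap_axial(np.degrees(0.5 * np.arctan2(2.0 * jxy, jxx - jyy)) + 90.0)
    disc = np.sqrt((jxx - jyy) ** 2 + 4.0 * jxy**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.where(trace > 0, disc / np.where(trace > 0, trace, 1.0), 0.0)
    coherence = np.clip(coherence, 0.0, 1.0)

    valid = trace > 0
    border = int(np.ceil(3.0 * sigma_window))
    if border > 0:
        edge = np.zeros_like(valid)
        if 2 * border < min(image.shape):
            edge[border:-border, border:-border] = True
        valid &= edge
    theta = np.where(valid, theta, np.nan)
    return OrientationFieldImage(theta_deg=theta, coherence=coherence, valid=valid)


def field_to_sample(
    field: OrientationFieldImage, coherence_min: float = 0.0
) -> OrientationSample:
    """Pool valid pixels with coherence >= ``coherence_min`` into a sample,
    weighted by coherence.  Raises ``ValueError`` if the selection is empty.
    """
    if not 0.0 <= coherence_min <= 1.0:
        raise ValueError("coherence_min must lie in [0, 1]")
    sel = field.valid & (field.coherence >= coherence_min) & np.isfinite(field.theta_deg)
    if not sel.any():
        raise EmptySampleError("no pixels pass the coherence threshold")
    return OrientationSample(field.theta_deg[sel], field.coherence[sel])
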