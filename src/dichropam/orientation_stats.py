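"""Axial circular statistics for orientation maps.

Fiber orientations are undirected: theta and theta + 180 deg are the same
axis.  All statistics therefore work on the doubled angles 2*theta, where
the axial data become ordinary circular data; results are mapped back by
halving.  The resultant vector length R of the doubled angles is the
orientation-uniformity index: R = 1 for perfectly aligned axes, R -> 0 for
an isotropic orientation distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import wrap_axial

__all__ = [
    "EmptySampleError",
    "OrientationSample",
    "OrientationSummary",
    "axial_resultant",
    "mean_angle_ci95",
    "polar_histogram",
    "roi_summary",
    "summarize",
    "sample_axial_vonmises",
]


class EmptySampleError(ValueError):
    """Raised when a pixel selection contains no usable orientations."""


@dataclass
class OrientationSample:
    """Axial angles (degrees, [-90, 90)) with optional non-negative weights."""

    angles_deg: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.angles_deg = wrap_axial(np.asarray(self.angles_deg, float).ravel())
        if not np.all(np.isfinite(self.angles_deg)):
            raise ValueError("angles must be finite")
        if self.weights is None:
            self.weights = np.ones_like(self.angles_deg)
        else:
            self.weights = np.asarray(self.weights, dtype=float).ravel()
            if self.weights.shape != self.angles_deg.shape:
                raise ValueError("weights must match angles in length")
            if np.any(self.weights < 0):
                raise ValueError("weights must be non-negative")
        if self.n == 0:
            raise EmptySampleError("empty sample")
        if self.weights.sum() == 0:
            raise ValueError("all weights are zero")

    @property
    def n(self) -> int:
        return self.angles_deg.size


@dataclass
class OrientationSummary:
    mean_angle_deg: float
    resultant_length: float
    ci95_deg: tuple[float, float]
    n_effective: float
    circ_sd_deg: float


def _complex_mean(angles_deg: np.ndarray, weights: np.ndarray) -> complex:
    """Weighted mean resultant of the doubled angles."""
    z = np.exp(1j * np.deg2rad(2.0 * angles_deg))
    return np.sum(weights * z) / np.sum(weights)


def axial_resultant(sample: OrientationSample) -> tuple[float, float]:
    """Axial mean angle and resultant vector length R.

    R = |mean of exp(2i theta)|; the mean angle is half the argument,
    wrapped to [-90, 90).  When R = 0 the mean is undefined and NaN is
    returned for the angle.
    """
    m = _complex_mean(sample.angles_deg, sample.weights)
    r = float(abs(m))
    if r < 1e-12:  # mean direction numerically undefined
        return float("nan"), r
    mean = float(wrap_axial(np.degrees(np.angle(m)) / 2.0))
    return mean, r


def circ_sd_deg(r: float) -> float:
    """Circular standard deviation on the axial scale, sqrt(-2 ln R) / 2."""
    if r <= 0:
        return float("inf")
    return float(np.degrees(np.sqrt(-2.0 * np.log(min(r, 1.0)))) / 2.0)


def mean_angle_ci95(
    sample: OrientationSample,
    method: str = "bootstrap",
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """95% confidence interval for the axial mean angle, degrees.

    method "bootstrap": seeded percentile bootstrap of the doubled-angle
    mean direction (default); method "fisher": large-sample normal
    interval using the circular standard error from the second
    trigonometric moment.  Both return (low, high) containing the point
    estimate modulo 180; the interval is reported around the point
    estimate and may extend beyond [-90, 90).
    """
    mean, r = axial_resultant(sample)
    if not np.isfinite(mean):
        raise ValueError("mean angle undefined (R = 0)")
    if method == "bootstrap":
        if sample.n < 10:
            raise ValueError("bootstrap CI needs at least 10 angles")
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, sample.n, size=(n_boot, sample.n))
        z = np.exp(1j * np.deg2rad(2.0 * sample.angles_deg))
        w = sample.weights
        m = (w[idx] * z[idx]).sum(axis=1) / w[idx].sum(axis=1)
        boot_means = np.degrees(np.angle(m)) / 2.0
        # center on the point estimate to avoid wrap artifacts at +/-90
        delta = wrap_axial(boot_means - mean)
        lo, hi = np.percentile(delta, [2.5, 97.5])
        return float(mean + lo), float(mean + hi)
    if method == "fisher":
        # second trig moment of doubled angles around the mean direction
        z = np.exp(1j * np.deg2rad(2.0 * sample.angles_deg))
        w = sample.weights / sample.weights.sum()
        mu2 = np.angle(_complex_mean(sample.angles_deg, sample.weights))
        alpha2 = float(np.sum(w * np.cos(2.0 * (np.angle(z) - mu2))))
        n_eff = float(sample.weights.sum() ** 2 / np.sum(sample.weights**2))
        se_doubled = np.sqrt(max(1.0 - alpha2, 0.0) / (2.0 * n_eff * r**2))
        half = 1.959963984540054 * np.degrees(se_doubled) / 2.0
        return float(mean - half), float(mean + half)
    raise ValueError(f"unknown CI method {method!r}")


def polar_histogram(
    sample: OrientationSample, n_bins: int = 18
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted histogram over equal-width bins partitioning [-90, 90).

    Returns (bin_edges, counts); counts sum to the total weight.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    edges = np.linspace(-90.0, 90.0, n_bins + 1)
    counts, _ = np.histogram(
        sample.angles_deg, bins=edges, weights=sample.weights
    )
    return edges, counts


def summarize(
    sample: OrientationSample,
    ci_method: str = "bootstrap",
    n_boot: int = 1000,
    seed: int = 0,
) -> OrientationSummary:
    """Full axial summary: mean angle, R, 95% CI and circular SD."""
    mean, r = axial_resultant(sample)
    ci = (
        mean_angle_ci95(sample, ci_method, n_boot=n_boot, seed=seed)
        if r > 0 and sample.n >= 10
        else (float("nan"), float("nan"))
    )
    n_eff = float(sample.weights.sum() ** 2 / np.sum(sample.weights**2))
    return OrientationSummary(
        mean_angle_deg=mean,
        resultant_length=r,
        ci95_deg=ci,
        n_effective=n_eff,
        circ_sd_deg=circ_sd_deg(r),
    )


def sample_axial_vonmises(
    mean_deg: float, kappa: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw axial angles whose doubled angles follow a von Mises law.

    The expected resultant length of the doubled angles is the Bessel
    ratio I1(kappa) / I0(kappa).
    """
    doubled = rng.vonmises(np.deg2rad(2.0 * mean_deg), kappa, size=n)
    return wrap_axial(np.degrees(doubled) / 2.0)


def roi_summary(
    result,
    roi_masks: dict[str, np.ndarray],
    weight_mode: str = "none",
    amplitude: np.ndarray | None = None,
    ci_seed: int = 0,
) -> pd.DataFrame:
    """Per-ROI statistics of a dichroism result.

    For each named boolean mask: mean and SD of DoLD over valid pixels,
    the axial mean, circular SD, resultant length and 95% CI of AoLD, and
    the pixel count.  ``weight_mode`` selects the weights of the axial
    statistics: "none" (unweighted), "amplitude" (requires ``amplitude``,
    e.g. the average map) or "dold".  ROIs with no valid pixels produce an
    n = 0 record rather than an error.
    """
    if weight_mode not in ("none", "amplitude", "dold"):
        raise ValueError("weight_mode must be 'none', 'amplitude' or 'dold'")
    if weight_mode == "amplitude" and amplitude is None:
        raise ValueError("weight_mode 'amplitude' requires an amplitude map")
    rows = []
    for name, mask in roi_masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != result.dold.shape:
            raise ValueError(f"ROI {name!r} mask shape does not match the maps")
        sel = mask & result.valid_mask & np.isfinite(result.aold_deg)
        n = int(sel.sum())
        if n == 0:
            rows.append(
                {
                    "region": name,
                    "n_pixels": 0,
                    "mean_dold": np.nan,
                    "sd_dold": np.nan,
                    "mean_aold_deg": np.nan,
                    "sd_aold_deg": np.nan,
                    "resultant_length": np.nan,
                    "ci95_low_deg": np.nan,
                    "ci95_high_deg": np.nan,
                }
            )
            continue
        dold_vals = result.dold[sel]
        if weight_mode == "amplitude":
            weights = amplitude[sel]
        elif weight_mode == "dold":
            weights = dold_vals
        else:
            weights = None
        sample = OrientationSample(result.aold_deg[sel], weights)
        summ = summarize(sample, seed=ci_seed)
        rows.append(
            {
                "region": name,
                "n_pixels": n,
                "mean_dold": float(dold_vals.mean()),
                "sd_dold": float(dold_vals.std(ddof=1)) if n > 1 else 0.0,
                "mean_aold_deg": summ.mean_angle_deg,
                "sd_aold_deg": summ.circ_sd_deg,
                "resultant_length": summ.resultant_length,
                "ci95_low_deg": summ.ci95_deg[0],
                "ci95_high_deg": summ.ci95_deg[1],
            }
        )
    columns = [
        "region",
        "n_pixels",
        "mean_dold",
        "sd_dold",
        "mean_aold_deg",
        "sd_aold_deg",
        "resultant_length",
        "ci95_low_deg",
        "ci95_high_deg",
    ]
    return pd.DataFrame(rows, columns=columns)
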