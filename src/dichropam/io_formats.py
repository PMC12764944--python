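"""Reading and writing stacks, result maps and summaries.

The on-disk contract is deliberately plain: multi-page float32 TIFF for
image stacks (one page per polarization state), a JSON or YAML sidecar
naming the angle and fluence of each page, float32 TIFF for result maps
(orientation angles in degrees, invalid pixels as NaN) and CSV for
tabular summaries.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import PolarizationStack, StackMetadata, canonical_angle
from .dichroism import DichroismResult

__all__ = [
    "read_stack",
    "write_stack",
    "read_sidecar",
    "write_results",
    "read_map",
    "write_map",
]


def read_sidecar(path: Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _sidecar_for(stack_path: Path) -> Path:
    for suffix in (".json", ".yaml", ".yml"):
        cand = Path(stack_path).with_suffix(suffix)
        if cand.exists():
            return cand
    raise FileNotFoundError(
        f"no JSON/YAML sidecar found next to {stack_path} "
        "(expected the same name with a .json or .yaml suffix)"
    )


def read_stack(path, meta_path=None) -> PolarizationStack:
    """Read a multi-page TIFF stack with its angle/fluence sidecar.

    The sidecar lists one angle per page; angles differing by 180 degrees
    are reduced to their axial equivalent.  Pages must share one shape.
    """
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else _sidecar_for(path)
    raw = read_sidecar(meta_path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None, ...]
    angles = [float(a) for a in raw["angles_deg"]]
    if len(angles) != pages.shape[0]:
        raise ValueError(
            f"sidecar lists {len(angles)} angles but the TIFF has {pages.shape[0]} pages"
        )
    meta = StackMetadata(
        angles_deg=angles,
        fluence=[float(f) for f in raw.get("fluence", [1.0] * len(angles))],
        pixel_size_um=float(raw.get("pixel_size_um", 1.0)),
        provenance=str(raw.get("provenance", "")),
    )
    images = {canonical_angle(a): np.asarray(p, float) for a, p in zip(angles, pages)}
    if len(images) != len(angles):
        raise ValueError("duplicate polarization angles (after axial reduction)")
    return PolarizationStack(images, meta)


def write_stack(stack: PolarizationStack, path, meta_path=None) -> Path:
    """Write a stack as float32 multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else path.with_suffix(".json")
    angles = stack.angles
    tifffile.imwrite(
        path,
        np.stack([stack[a] for a in angles]).astype(np.float32),
        photometric="minisblack",
    )
    sidecar = {
        "angles_deg": angles,
        "fluence": [stack.meta.fluence_for(a) for a in angles],
        "pixel_size_um": stack.meta.pixel_size_um,
        "provenance": stack.meta.provenance,
    }
    meta_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return path


def write_map(image: np.ndarray, path) -> Path:
    """Write a single float map as float32 TIFF (NaN marks invalid pixels)."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, np.float32))
    return path


def read_map(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


def write_results(
    result: DichroismResult, summaries: pd.DataFrame | None, out_dir
) -> dict[str, Path]:
    """Write DoLD/AoLD/mask/flags maps and the ROI summary table.

    AoLD is written in degrees with invalid pixels as NaN; the summary CSV
    keeps its header even when there are no ROIs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # maps carry their own NaN sentinels; flags/mask give the full diagnosis
    paths = {
        "dold": write_map(result.dold, out / "dold.tif"),
        "aold": write_map(result.aold_deg, out / "aold.tif"),
        "mask": write_map(result.valid_mask.astype(np.float32), out / "mask.tif"),
        "flags": write_map(result.flags.astype(np.float32), out / "flags.tif"),
    }
    if summaries is not None:
        csv = out / "summary.csv"
        summaries.to_csv(csv, index=False, float_format="%.10g")
        paths["summary"] = csv
    return paths
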