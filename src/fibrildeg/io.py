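"""Readers and writers for the pipeline's file formats.

Tables are CSV (UTF-8, header row, '.' decimal separator); images are 8-bit
grayscale TIFF; configuration is YAML.  Column names carry units
(diameter_nm, csa_nm2, time_h, ...).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .piecewise import FibrilTrace
from .population import MixtureSpec

__all__ = [
    "read_image",
    "write_image",
    "read_traces",
    "write_traces",
    "load_mixture_spec",
    "save_mixture_spec",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale TIFF/PNG as float64."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    img = np.asarray(img, float)
    if img.ndim == 3:  # collapse RGB
        img = img.mean(axis=-1)
    return img


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write an intensity image as 8-bit grayscale TIFF (clipped to [0,255])."""
    arr = np.clip(np.round(np.asarray(image, float)), 0, 255).astype(np.uint8)
    tifffile.imwrite(Path(path), arr)


def read_traces(path: str | Path, pixel_size: float) -> list[FibrilTrace]:
    """Read fibril centerlines from a long-format trace CSV.

    Expected columns: image_id, fibril_id, vertex_index, x_px, y_px.
    """
    df = pd.read_csv(path)
    required = {"image_id", "fibril_id", "vertex_index", "x_px", "y_px"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    traces = []
    for (image_id, fid), grp in df.groupby(["image_id", "fibril_id"], sort=True):
        grp = grp.sort_values("vertex_index")
        traces.append(
            FibrilTrace(
                points=grp[["x_px", "y_px"]].to_numpy(float),
                pixel_size=pixel_size,
                image_id=str(image_id),
                fibril_id=int(fid),
            )
        )
    return traces


def write_traces(path: str | Path, traces: list[FibrilTrace]) -> None:
    rows = []
    for t in traces:
        for i, (x, y) in enumerate(t.points):
            rows.append(
                {
                    "image_id": t.image_id,
                    "fibril_id": t.fibril_id,
                    "vertex_index": i,
                    "x_px": x,
                    "y_px": y,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_mixture_spec(path: str | Path) -> MixtureSpec:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return MixtureSpec.from_dict(cfg)


def save_mixture_spec(path: str | Path, spec: MixtureSpec) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)
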