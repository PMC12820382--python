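"""Synthetic SEM-like images of banded collagen fibrils with known truth.

Each fibril is rendered as a smooth tube along a given centerline: a flat-top
radial profile with an error-function edge ramp (about 2 px wide), an axial
sinusoidal intensity modulation at the D-band period, composited over a
uniform background with optional additive Gaussian noise.  Alongside the
image, a ground-truth table records every fibril's true mean diameter,
orientation, curvature, and band period — the oracle for the measurement
pipeline.

The default calibration is 4 nm/px, which puts a 250-nm measurement piece at
about 62 px and keeps the 36-70 nm D-band search window comfortably below
the Nyquist period of 8 nm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import erf

from .geometry import (
    polyline_arc_length,
    resample_polyline,
    segment_angle_deg,
    wrap_half_turn,
)

__all__ = [
    "ImageSpec",
    "SyntheticFibrilSpec",
    "render",
    "make_fixture_suite",
    "line_centerline",
    "arc_centerline",
]

_DENSE_STEP_PX = 0.25  # centerline sampling for rendering
_EDGE_SIGMA_PX = 1.0  # erf edge ramp scale (~2 px wide transition)


@dataclass(frozen=True)
class ImageSpec:
    width: int = 704
    height: int = 192
    pixel_size: float = 4.0  # nm per pixel
    background: float = 40.0  # intensity level (8-bit scale)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.width < 64 or self.height < 64:
            raise ValueError("image dimensions must be >= 64 px")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticFibrilSpec:
    """One fibril: centerline control points (px) plus intensity parameters.

    ``diameter`` is either a constant (nm) or a (start, end) pair for a
    linear taper along arc length.  ``band_period`` is the axial D-band
    period in nm; ``band_contrast`` the modulation depth as a fraction of the
    fibril intensity.
    """

    centerline: np.ndarray  # (N, 2) px, (x, y)
    diameter: float | tuple[float, float] = 100.0  # nm
    band_period: float = 52.6  # nm
    band_contrast: float = 0.2
    base_intensity: float = 160.0

    def __post_init__(self):
        self.centerline = np.asarray(self.centerline, float)
        d = np.atleast_1d(np.asarray(self.diameter, float))
        if np.any(d <= 0):
            raise ValueError("diameter must be > 0 nm")
        if self.band_period <= 0:
            raise ValueError("band_period must be > 0 nm")

    def diameter_at(self, frac: np.ndarray) -> np.ndarray:
        """Local diameter (nm) at fractional arc position ``frac`` in [0, 1]."""
        if np.isscalar(self.diameter):
            return np.full_like(np.asarray(frac, float), float(self.diameter))
        d0, d1 = self.diameter
        return d0 + (d1 - d0) * np.asarray(frac, float)

    @property
    def mean_diameter(self) -> float:
        if np.isscalar(self.diameter):
            return float(self.diameter)
        return float(np.mean(self.diameter))


def line_centerline(start, angle_deg: float, length_nm: float, pixel_size: float,
                    n_points: int = 25) -> np.ndarray:
    """Straight centerline of a given length and heading (image coords)."""
    length_px = length_nm / pixel_size
    t = np.linspace(0.0, length_px, n_points)
    a = np.radians(angle_deg)
    x0, y0 = start
    return np.column_stack([x0 + t * np.cos(a), y0 + t * np.sin(a)])


def arc_centerline(center, radius_nm: float, start_deg: float, end_deg: float,
                   pixel_size: float, n_points: int = 80) -> np.ndarray:
    """Circular-arc centerline (constant curvature (180/pi)/R deg per length)."""
    r_px = radius_nm / pixel_size
    ang = np.radians(np.linspace(start_deg, end_deg, n_points))
    cx, cy = center
    return np.column_stack([cx + r_px * np.cos(ang), cy + r_px * np.sin(ang)])


def _true_piece_orientations(dense: np.ndarray, pixel_size: float,
                             piece_length_nm: float = 250.0) -> np.ndarray:
    pts = resample_polyline(dense, piece_length_nm / pixel_size)
    if pts.shape[0] < 2:
        return np.array([])
    return np.array([segment_angle_deg(pts[i], pts[i + 1]) for i in range(pts.shape[0] - 1)])


def _true_curvature(dense: np.ndarray, pixel_size: float,
                    piece_length_nm: float = 250.0) -> float:
    ori = _true_piece_orientations(dense, pixel_size, piece_length_nm)
    if ori.size < 2:
        return 0.0
    diffs = wrap_half_turn(np.diff(ori))
    span_um = (ori.size - 1) * piece_length_nm / 1000.0
    return float(np.sum(np.abs(diffs)) / span_um)


def render(
    image_spec: ImageSpec, fibril_specs: list[SyntheticFibrilSpec]
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render fibrils into a grayscale image and return it with its truth table.

    The image is float64 on the 8-bit scale [0, 255]; bit-identical for a
    fixed seed.  The truth table has one row per fibril with true mean
    diameter, overall orientation, curvature on the 250-nm piece grid, band
    period, and arc length.
    """
    h, w = image_spec.height, image_spec.width
    canvas = np.full((h, w), image_spec.background, float)
    truth_rows = []

    for fid, fib in enumerate(fibril_specs):
        dense = resample_polyline(fib.centerline, _DENSE_STEP_PX)
        seg = np.hypot(*np.diff(dense, axis=0).T)
        s_px = np.concatenate([[0.0], np.cumsum(seg)])
        total_px = s_px[-1]
        frac = s_px / total_px
        diam_nm = fib.diameter_at(frac)
        rad_px = diam_nm / (2.0 * image_spec.pixel_size)
        max_rad = rad_px.max()

        margin = max_rad + 4 * _EDGE_SIGMA_PX
        if (
            dense[:, 0].min() < margin - 0.5
            or dense[:, 0].max() > w - 1 - margin + 0.5
            or dense[:, 1].min() < margin - 0.5
            or dense[:, 1].max() > h - 1 - margin + 0.5
        ):
            raise ValueError(f"fibril {fid} exceeds the image frame")

        x0 = max(0, int(np.floor(dense[:, 0].min() - margin)))
        x1 = min(w, int(np.ceil(dense[:, 0].max() + margin)) + 1)
        y0 = max(0, int(np.floor(dense[:, 1].min() - margin)))
        y1 = min(h, int(np.ceil(dense[:, 1].max() + margin)) + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        pix = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)

        tree = cKDTree(dense)
        dist, idx = tree.query(pix, workers=-1)
        s_nm = s_px[idx] * image_spec.pixel_size
        local_rad = rad_px[idx]

        band = 1.0 + fib.band_contrast * np.sin(2.0 * np.pi * s_nm / fib.band_period)
        envelope = 0.5 * (1.0 - erf((dist - local_rad) / (_EDGE_SIGMA_PX * np.sqrt(2.0))))
        val = fib.base_intensity * band * envelope
        patch = canvas[y0:y1, x0:x1]
        np.maximum(patch, image_spec.background + val.reshape(patch.shape), out=patch)

        truth_rows.append(
            {
                "fibril_id": fid,
                "mean_diameter_nm": float(np.mean(diam_nm)),
                "orientation_deg": segment_angle_deg(dense[0], dense[-1]),
                "curvature_deg_per_um": _true_curvature(dense, image_spec.pixel_size),
                "band_period_nm": fib.band_period,
                "arc_length_nm": total_px * image_spec.pixel_size,
            }
        )

    if image_spec.noise_sd > 0:
        rng = np.random.default_rng(image_spec.seed)
        canvas = canvas + rng.normal(0.0, image_spec.noise_sd, canvas.shape)
    canvas = np.clip(canvas, 0.0, 255.0)
    return canvas, pd.DataFrame(truth_rows)


@dataclass
class Scene:
    name: str
    image: np.ndarray
    truth: pd.DataFrame
    traces: list[np.ndarray]  # one centerline (px) per fibril
    image_spec: ImageSpec


def _write_scene(scene: Scene, out_dir: Path) -> None:
    import tifffile

    out_dir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        out_dir / f"{scene.name}.tif", np.round(scene.image).astype(np.uint8)
    )
    scene.truth.to_csv(out_dir / f"{scene.name}_truth.csv", index=False)
    rows = []
    for fid, pts in enumerate(scene.traces):
        for i, (x, y) in enumerate(pts):
            rows.append(
                {"image_id": scene.name, "fibril_id": fid, "vertex_index": i,
                 "x_px": x, "y_px": y}
            )
    pd.DataFrame(rows).to_csv(out_dir / f"{scene.name}_traces.csv", index=False)


def make_fixture_suite(
    seed: int = 0,
    pixel_size: float = 4.0,
    out_dir: str | Path | None = None,
) -> dict[str, Scene]:
    """Generate the standard synthetic test scenes.

    Straight, rotated, tapered and curved fibrils; a ladder of band periods
    from 40 to 65 nm; a noise ladder; and a control-vs-enzyme scene pair with
    diameters drawn from the extensor-control and degraded mixtures.  All
    scenes are deterministic given ``seed``; if ``out_dir`` is set they are
    also written as 8-bit TIFFs with truth and trace CSVs.
    """
    from .population import EXTENSOR_CONTROL_MIXTURE, MixtureComponent, MixtureSpec, sample_population

    rng = np.random.default_rng(seed)
    scenes: dict[str, Scene] = {}

    def add(name, spec, fibs):
        img, truth = render(spec, fibs)
        scenes[name] = Scene(
            name=name, image=img, truth=truth,
            traces=[f.centerline.copy() for f in fibs], image_spec=spec,
        )

    length_nm = 2500.0
    base = ImageSpec(width=704, height=192, pixel_size=pixel_size, seed=seed)

    add("straight_d100", base,
        [SyntheticFibrilSpec(line_centerline((20, 96), 0.0, length_nm, pixel_size))])
    add("rotated_30",
        ImageSpec(width=640, height=448, pixel_size=pixel_size, seed=seed),
        [SyntheticFibrilSpec(line_centerline((25, 40), 30.0, length_nm, pixel_size))])
    add("tapered_80_120", base,
        [SyntheticFibrilSpec(line_centerline((20, 96), 0.0, length_nm, pixel_size),
                             diameter=(80.0, 120.0))])

    # 5 deg heading change per 250-nm piece -> curvature 20 deg/um -> R = (180/pi)/20 um
    r20 = (180.0 / np.pi) / 20.0 * 1000.0
    span20 = np.degrees(length_nm / r20)
    add("curved_20degum",
        ImageSpec(width=704, height=448, pixel_size=pixel_size, seed=seed),
        [SyntheticFibrilSpec(arc_centerline(
            (352, 60 + r20 / pixel_size), r20, -90 - span20 / 2, -90 + span20 / 2,
            pixel_size))])
    r5um = 5000.0
    span5 = np.degrees(length_nm / r5um)
    add("arc_r5um",
        ImageSpec(width=704, height=256, pixel_size=pixel_size, seed=seed),
        [SyntheticFibrilSpec(arc_centerline(
            (352, 60 + r5um / pixel_size), r5um, -90 - span5 / 2, -90 + span5 / 2,
            pixel_size))])

    for period in (40.0, 45.0, 50.0, 52.6, 55.0, 60.0, 65.0):
        add(f"band_{period:g}", base,
            [SyntheticFibrilSpec(line_centerline((20, 96), 0.0, length_nm, pixel_size),
                                 band_period=period)])

    for noise in (5.0, 10.0, 20.0):
        add(f"noise_{noise:g}",
            ImageSpec(width=704, height=192, pixel_size=pixel_size,
                      noise_sd=noise, seed=seed),
            [SyntheticFibrilSpec(line_centerline((20, 96), 0.0, length_nm, pixel_size))])

    # Control vs enzyme scene pair: several near-parallel fibrils, diameters
    # from the extensor-control mixture and a degraded (left-shifted) mixture.
    degraded = MixtureSpec(components=[MixtureComponent(0.36, 54.7, 20.0),
                                       MixtureComponent(0.64, 90.3, 22.0)])
    for name, mix, ori_sd in (("scene_control", EXTENSOR_CONTROL_MIXTURE, 8.0),
                              ("scene_enzyme", degraded, 30.0)):
        spec = ImageSpec(width=704, height=1152, pixel_size=pixel_size,
                         noise_sd=4.0, seed=int(rng.integers(2**31)))
        diams = sample_population(mix, 5, rng=rng).diameters
        fibs = []
        for i, d in enumerate(diams):
            ang = float(np.clip(rng.normal(0.0, ori_sd), -22, 22))
            fibs.append(SyntheticFibrilSpec(
                line_centerline((40, 260 + 150 * i), ang, 2200.0, pixel_size),
                diameter=float(d)))
        add(name, spec, fibs)

    if out_dir is not None:
        for scene in scenes.values():
            _write_scene(scene, Path(out_dir))
    return scenes
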