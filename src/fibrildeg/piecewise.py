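"""Piecewise fibril morphometry from SEM images and traced centerlines.

The measurement core works from a user-supplied (semi-manual) centerline
trace per fibril.  The trace is resampled into consecutive 250-nm pieces;
within each piece the fibril width is measured on several intensity profiles
taken perpendicular to the piece axis (edge = steepest intensity gradient on
either side of the centerline), and the piece orientation is taken from the
endpoint chord.  Piece tables are then reduced to fibril-level statistics:

* mean and SD of piecewise diameter (the SD quantifies diameter variation
  along the fibril),
* mean orientation (axial, half-turn aware),
* curvature — cumulative absolute change in piecewise orientation per
  micrometer of fibril length,
* image-normalized alignment — each fibril's orientation minus the image
  mean, whose dispersion measures how well fibrils in an image co-align.

Fibrils must be traceable for at least 2 um with both edges visible; shorter
traces are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates, uniform_filter1d

from .geometry import (
    axial_mean_deg,
    polyline_arc_length,
    resample_polyline,
    segment_angle_deg,
    wrap_half_turn,
)

__all__ = [
    "FibrilTrace",
    "PieceMeasurement",
    "FibrilMeasurement",
    "detect_edges_piecewise",
    "fibril_stats",
    "curvature",
    "image_alignment",
]

MIN_TRACE_LENGTH_NM = 2000.0
STATION_FRACTIONS = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass
class FibrilTrace:
    """An ordered fibril centerline in pixel coordinates (x right, y down)."""

    points: np.ndarray  # (N, 2)
    pixel_size: float  # nm/px
    image_id: str = ""
    fibril_id: int = 0

    def __post_init__(self):
        self.points = np.asarray(self.points, float)
        if self.points.ndim != 2 or self.points.shape[0] < 2:
            raise ValueError("trace needs >= 2 vertices")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def arc_length_nm(self) -> float:
        return polyline_arc_length(self.points) * self.pixel_size


@dataclass
class PieceMeasurement:
    piece_index: int
    diameter: float  # nm
    orientation: float  # degrees in (-90, 90]
    center: tuple[float, float]  # px
    nominal_length: float = 250.0  # nm


@dataclass
class FibrilMeasurement:
    fibril_id: int
    mean_diameter: float
    sd_diameter: float
    mean_orientation: float
    curvature: float  # deg/um
    n_pieces: int
    normalized_orientation: float = np.nan  # filled by image_alignment


def _perpendicular_width_px(
    image: np.ndarray,
    center: np.ndarray,
    direction: np.ndarray,
    max_radius_px: float,
    smooth_px: float,
    step_px: float = 0.5,
) -> float | None:
    """Width (px) between the steepest opposite-signed gradient extrema.

    Samples the intensity along the perpendicular through ``center``; the
    fibril edge on each side is the location of the steepest rising (left)
    and falling (right) gradient.  Returns None if the profile leaves the
    frame.
    """
    normal = np.array([-direction[1], direction[0]])
    offsets = np.arange(-max_radius_px, max_radius_px + step_px / 2, step_px)
    pts = center[None, :] + offsets[:, None] * normal[None, :]
    h, w = image.shape
    if (
        pts[:, 0].min() < 0 or pts[:, 0].max() > w - 1
        or pts[:, 1].min() < 0 or pts[:, 1].max() > h - 1
    ):
        return None
    # map_coordinates expects (row, col) = (y, x)
    prof = map_coordinates(image, [pts[:, 1], pts[:, 0]], order=1)
    win = max(2, int(round(smooth_px / step_px)))
    prof = uniform_filter1d(prof, win)
    grad = np.gradient(prof, offsets)
    neg = offsets < 0
    pos = offsets > 0
    if not neg.any() or not pos.any():
        return None
    left = offsets[neg][np.argmax(grad[neg])]  # rising into the fibril
    right = offsets[pos][np.argmin(grad[pos])]  # falling out of it
    return float(right - left)


def detect_edges_piecewise(
    image: np.ndarray,
    trace: FibrilTrace,
    piece_length_nm: float = 250.0,
    n_stations: int = 5,
    max_radius_nm: float = 200.0,
    smooth_px: float = 3.0,
) -> list[PieceMeasurement]:
    """Measure diameter and orientation in consecutive 250-nm pieces.

    The centerline is resampled to equal arc-length pieces (the trailing
    sub-piece remainder is discarded).  Per piece, the diameter is the mean
    of ``n_stations`` perpendicular edge-to-edge widths and the orientation
    comes from the piece's endpoint chord.  Pieces whose profiles exit the
    frame are excluded.
    """
    if trace.arc_length_nm < MIN_TRACE_LENGTH_NM:
        raise ValueError(
            f"trace arc length {trace.arc_length_nm:.0f} nm is below the "
            f"{MIN_TRACE_LENGTH_NM:.0f} nm minimum"
        )
    piece_px = piece_length_nm / trace.pixel_size
    if piece_px < 4:
        raise ValueError("piece length must be >= 4 px")
    # Fine resampling so stations land accurately inside each piece.
    fine_step = piece_px / 50.0
    fine = resample_polyline(trace.points, fine_step)
    n_pieces = int((fine.shape[0] - 1) // 50)

    fracs = (
        STATION_FRACTIONS
        if n_stations == len(STATION_FRACTIONS)
        else tuple((i + 0.5) / n_stations for i in range(n_stations))
    )
    max_radius_px = max_radius_nm / trace.pixel_size
    image = np.asarray(image, float)

    pieces = []
    for k in range(n_pieces):
        start, end = fine[50 * k], fine[50 * (k + 1)]
        chord = end - start
        direction = chord / np.linalg.norm(chord)
        widths = []
        ok = True
        for f in fracs:
            station = fine[50 * k + int(round(f * 50))]
            w_px = _perpendicular_width_px(
                image, station, direction, max_radius_px, smooth_px
            )
            if w_px is None:
                ok = False
                break
            widths.append(w_px)
        if not ok:
            continue
        center = fine[50 * k + 25]
        pieces.append(
            PieceMeasurement(
                piece_index=k,
                diameter=float(np.mean(widths)) * trace.pixel_size,
                orientation=segment_angle_deg(start, end),
                center=(float(center[0]), float(center[1])),
                nominal_length=piece_length_nm,
            )
        )
    return pieces


def curvature(pieces: list[PieceMeasurement]) -> float:
    """Cumulative absolute piecewise orientation change per um of length.

    Successive orientation differences are wrapped onto the half-turn
    (fibrils are undirected) before taking absolute values; the sum is
    normalized by the arc length spanned between the first and last piece.
    """
    if len(pieces) < 2:
        raise ValueError("curvature needs >= 2 pieces")
    ori = np.array([p.orientation for p in pieces])
    diffs = wrap_half_turn(np.diff(ori))
    # index-aware span so excluded (out-of-frame) pieces don't shrink it
    span_pieces = pieces[-1].piece_index - pieces[0].piece_index
    span_um = span_pieces * pieces[0].nominal_length / 1000.0
    return float(np.sum(np.abs(diffs)) / span_um)


def fibril_stats(pieces: list[PieceMeasurement], fibril_id: int = 0) -> FibrilMeasurement:
    """Fibril-level mean/SD diameter, mean orientation, and curvature."""
    if len(pieces) < 2:
        raise ValueError("fibril statistics need >= 2 pieces")
    diams = np.array([p.diameter for p in pieces])
    ori = np.array([p.orientation for p in pieces])
    return FibrilMeasurement(
        fibril_id=fibril_id,
        mean_diameter=float(diams.mean()),
        sd_diameter=float(diams.std(ddof=1)),
        mean_orientation=axial_mean_deg(ori),
        curvature=curvature(pieces),
        n_pieces=len(pieces),
    )


def image_alignment(fibrils: list[FibrilMeasurement]) -> tuple[list[FibrilMeasurement], float]:
    """Normalize fibril orientations to the image mean; return the dispersion.

    Each fibril's mean orientation has the image's axial mean orientation
    subtracted (wrapped onto the half-turn), making alignment comparable
    across images regardless of stage rotation.  Returns the updated fibril
    records and the SD (degrees, ddof=1) of the normalized orientations.
    """
    if len(fibrils) < 2:
        raise ValueError("alignment dispersion needs >= 2 fibrils in the image")
    mean_ori = axial_mean_deg([f.mean_orientation for f in fibrils])
    normalized = wrap_half_turn(
        np.array([f.mean_orientation for f in fibrils]) - mean_ori
    )
    for f, v in zip(fibrils, normalized):
        f.normalized_orientation = float(v)
    return fibrils, float(np.std(normalized, ddof=1))


def measure_image(
    image: np.ndarray,
    traces: list[FibrilTrace],
    piece_length_nm: float = 250.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full piecewise pipeline on one image.

    Returns (piece table, fibril table) as DataFrames; the fibril table
    includes image-normalized orientations when >= 2 fibrils are present.
    """
    piece_rows = []
    fibrils = []
    for trace in traces:
        pieces = detect_edges_piecewise(image, trace, piece_length_nm)
        for p in pieces:
            piece_rows.append(
                {
                    "image_id": trace.image_id,
                    "fibril_id": trace.fibril_id,
                    "piece_index": p.piece_index,
                    "diameter_nm": p.diameter,
                    "orientation_deg": p.orientation,
                    "center_x_px": p.center[0],
                    "center_y_px": p.center[1],
                }
            )
        fibrils.append(fibril_stats(pieces, fibril_id=trace.fibril_id))
    if len(fibrils) >= 2:
        fibrils, _ = image_alignment(fibrils)
    fib_rows = [
        {
            "fibril_id": f.fibril_id,
            "mean_diameter_nm": f.mean_diameter,
            "sd_diameter_nm": f.sd_diameter,
            "mean_orientation_deg": f.mean_orientation,
            "normalized_orientation_deg": f.normalized_orientation,
            "curvature_deg_per_um": f.curvature,
            "n_pieces": f.n_pieces,
        }
        for f in fibrils
    ]
    return pd.DataFrame(piece_rows), pd.DataFrame(fib_rows)
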