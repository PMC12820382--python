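"""Polyline and axial-angle helpers shared by the image modules.

Image coordinates are (x, y) in pixels, 0-based, origin top-left, x
rightward, y downward.  Fibrils are undirected, so orientations live on the
half-turn: degrees in (-90, 90] measured from the image x-axis.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "polyline_arc_length",
    "resample_polyline",
    "wrap_half_turn",
    "axial_mean_deg",
    "segment_angle_deg",
]


def polyline_arc_length(points: np.ndarray) -> float:
    """Total arc length (same units as coordinates) of an ordered polyline."""
    points = np.asarray(points, float)
    return float(np.sum(np.hypot(*np.diff(points, axis=0).T)))


def resample_polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample an ordered polyline at uniform arc-length ``spacing``.

    Returns points at arc positions 0, spacing, 2*spacing, ... including the
    start but not necessarily the exact end (the trailing remainder is kept
    only if it lands on the grid).
    """
    points = np.asarray(points, float)
    if points.ndim != 2 or points.shape[0] < 2:
        raise ValueError("polyline needs >= 2 points")
    seg = np.hypot(*np.diff(points, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    targets = np.arange(0.0, total + spacing * 1e-9, spacing)
    x = np.interp(targets, s, points[:, 0])
    y = np.interp(targets, s, points[:, 1])
    return np.column_stack([x, y])


def wrap_half_turn(angle_deg):
    """Wrap angles (degrees) into (-90, 90]."""
    a = np.asarray(angle_deg, float)
    wrapped = (a + 90.0) % 180.0 - 90.0
    wrapped = np.where(wrapped == -90.0, 90.0, wrapped)
    return float(wrapped) if wrapped.ndim == 0 else wrapped


def segment_angle_deg(p0, p1) -> float:
    """Orientation of the chord p0->p1 in (-90, 90] degrees."""
    dx, dy = np.asarray(p1, float) - np.asarray(p0, float)
    return wrap_half_turn(np.degrees(np.arctan2(dy, dx)))


def axial_mean_deg(angles_deg) -> float:
    """Axial (half-turn) mean of orientations in degrees.

    Angles are doubled, averaged on the circle, and halved — robust near the
    +/-90 wrap where the arithmetic mean fails.
    """
    a = np.radians(np.asarray(angles_deg, float)) * 2.0
    mean = np.arctan2(np.sin(a).mean(), np.cos(a).mean()) / 2.0
    return wrap_half_turn(np.degrees(mean))
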