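"""Polyline geometry helpers shared across the tractography modules.

A streamline is represented throughout the package as a float ``(N, 3)``
NumPy array of world coordinates in millimetres, with ``N >= 2`` and
consecutive points distinct.
"""

from __future__ import annotations

import numpy as np


def as_streamline(points) -> np.ndarray:
    """Validate and return a streamline as a float64 ``(N, 3)`` array."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"streamline must be (N, 3), got shape {pts.shape}")
    if pts.shape[0] < 2:
        raise ValueError("streamline needs at least 2 points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0):
        raise ValueError("consecutive streamline points must be distinct")
    return pts


def segment_lengths(points: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.diff(points, axis=0), axis=1)


def arc_length(points: np.ndarray) -> float:
    """Total polyline length in mm."""
    return float(segment_lengths(points).sum())


def arc_fractions(points: np.ndarray) -> np.ndarray:
    """Cumulative arc-length fraction in [0, 1] at each point."""
    seg = segment_lengths(points)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total == 0:
        return np.zeros(len(points))
    return cum / total


def resample_streamline(points: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a polyline to ``n_points`` equidistant arc-length samples.

    Linear interpolation along the polyline; endpoints are preserved
    exactly.
    """
    pts = np.asarray(points, dtype=float)
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    frac = arc_fractions(pts)
    target = np.linspace(0.0, 1.0, n_points)
    out = np.empty((n_points, 3))
    for k in range(3):
        out[:, k] = np.interp(target, frac, pts[:, k])
    return out
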