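"""Closed-curve helpers shared by the generator and the curvature module.

Coordinate convention throughout the package: x rightward, y downward
(image convention); physical position in um = pixel index * pixel size.
A contour is "counterclockwise" when its shoelace signed area is positive
in this frame, which is the orientation produced by increasing polar
angle theta with x = r cos(theta), y = r sin(theta).
"""

from __future__ import annotations

import numpy as np


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon (first point not repeated)."""
    x = points[:, 0]
    y = points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_centroid(points: np.ndarray) -> np.ndarray:
    """Area centroid of a closed polygon (first point not repeated)."""
    x = points[:, 0]
    y = points[:, 1]
    xn = np.roll(x, -1)
    yn = np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * np.sum(cross)
    if abs(area) < 1e-300:
        return points.mean(axis=0)
    cx = np.sum((x + xn) * cross) / (6.0 * area)
    cy = np.sum((y + yn) * cross) / (6.0 * area)
    return np.array([cx, cy])


def ensure_counterclockwise(points: np.ndarray) -> np.ndarray:
    if signed_area(points) < 0:
        return points[::-1].copy()
    return points


def arclengths(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Cumulative arclength at each vertex and the closed perimeter.

    Returns (s, perimeter) with s[0] = 0 and s measured along the closed
    polyline; perimeter includes the closing segment back to points[0].
    """
    seg = np.linalg.norm(np.diff(points, axis=0, append=points[:1]), axis=1)
    s = np.concatenate(([0.0], np.cumsum(seg[:-1])))
    return s, float(seg.sum())


def resample_closed(points: np.ndarray, step: float | None = None,
                    n_points: int | None = None) -> np.ndarray:
    """Resample a closed polyline to uniform arclength spacing.

    Exactly one of `step` (target spacing) or `n_points` must be given.
    The first output point coincides with the original first vertex.
    """
    if (step is None) == (n_points is None):
        raise ValueError("give exactly one of step or n_points")
    s, perim = arclengths(points)
    if n_points is None:
        n_points = max(3, int(round(perim / step)))
    targets = np.arange(n_points) * (perim / n_points)
    closed = np.vstack([points, points[:1]])
    s_closed = np.concatenate([s, [perim]])
    x = np.interp(targets, s_closed, closed[:, 0])
    y = np.interp(targets, s_closed, closed[:, 1])
    return np.column_stack([x, y])


def interp_periodic(s_query: np.ndarray, s: np.ndarray, values: np.ndarray,
                    period: float) -> np.ndarray:
    """Linear interpolation of values(s) on a closed curve of given period."""
    sq = np.mod(s_query, period)
    s_ext = np.concatenate([s, [s[0] + period]])
    v_ext = np.concatenate([values, [values[0]]]) if values.ndim == 1 else \
        np.vstack([values, values[:1]])
    if values.ndim == 1:
        return np.interp(sq, s_ext, v_ext)
    out = np.empty((len(sq), values.shape[1]))
    for j in range(values.shape[1]):
        out[:, j] = np.interp(sq, s_ext, v_ext[:, j])
    return out
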