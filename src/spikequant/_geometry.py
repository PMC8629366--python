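"""Shared planar geometry helpers for the two-quadrangle spike model.

Coordinate convention used throughout the package: x runs along the spike
centerline from the base (x = 0) to the tip (x = L), in mm; y is the
perpendicular offset from the centerline, positive above it.  The spike body
outline is the closed hexagon

    (0, 0) -> (xu1, yu1) -> (xu2, yu2) -> (L, 0) -> (xb2, -yb2) -> (xb1, -yb1)

i.e. two quadrilaterals (upper and lower) sharing the base and tip vertices
on the centerline.
"""

from __future__ import annotations

import numpy as np

QUAD_PARAM_NAMES = ("xu1", "yu1", "xu2", "yu2", "xb1", "yb1", "xb2", "yb2", "L")


def polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a simple polygon given as an (N, 2) vertex array."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polyline_length(points: np.ndarray) -> float:
    """Total length of an open polyline given as an (N, 2) array."""
    p = np.asarray(points, dtype=float)
    if len(p) < 2:
        return 0.0
    return float(np.sum(np.hypot(*np.diff(p, axis=0).T)))


def body_polygon(params: dict[str, float]) -> np.ndarray:
    """Closed body outline (6 vertices, mm) from the nine quad parameters."""
    p = params
    return np.array(
        [
            (0.0, 0.0),
            (p["xu1"], p["yu1"]),
            (p["xu2"], p["yu2"]),
            (p["L"], 0.0),
            (p["xb2"], -p["yb2"]),
            (p["xb1"], -p["yb1"]),
        ]
    )


def upper_chain(x: np.ndarray, xu1: float, yu1: float, xu2: float, yu2: float, L: float) -> np.ndarray:
    """Piecewise-linear upper half-width profile at positions ``x``."""
    return np.interp(x, [0.0, xu1, xu2, L], [0.0, yu1, yu2, 0.0])


def lower_chain(x: np.ndarray, xb1: float, yb1: float, xb2: float, yb2: float, L: float) -> np.ndarray:
    """Piecewise-linear lower half-width profile (positive values) at ``x``."""
    return np.interp(x, [0.0, xb1, xb2, L], [0.0, yb1, yb2, 0.0])


def quad_area(params: dict[str, float]) -> float:
    """Analytic body area (mm^2): sum of the two quadrilateral areas."""
    return polygon_area(body_polygon(params))
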