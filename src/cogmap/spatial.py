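"""Spatial-distribution statistics of response types in the image plane.

To compare soma positions across ganglia of different sizes, each neuron's
position is normalised against the geometry of its own preparation: a convex
polygon is drawn around the outer neurons, its (area) centroid is found, and
the neuron's radial position is expressed as

    d_ratio = d(neuron, centroid) / d(border, centroid)

where the border point lies on the ray from the centroid through the neuron
(so interior neurons get d_ratio <= 1 and hull vertices get 1).  Direction
is the angle of that ray; directional variability of a group of neurons is
the circular variance ``1 - R̄`` (R̄ = mean resultant length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "NeuronGeometry",
    "hull_and_centroid",
    "normalized_position",
    "angular_variance",
    "population_geometry",
]


@dataclass
class NeuronGeometry:
    """Normalised radial position and direction of one soma."""

    neuron_id: str
    xy: tuple[float, float]
    angle: float  # radians from centroid; NaN when at the centroid
    d_ratio: float
    at_centroid: bool = False


def hull_and_centroid(
    points: Sequence[tuple[float, float]], centroid_method: str = "area"
) -> tuple[Polygon, tuple[float, float]]:
    """Convex polygon around the outer points and its centroid.

    ``centroid_method`` is ``"area"`` (polygon area centroid, default) or
    ``"vertices"`` (mean of hull vertices).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least three 2-D points")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise ValueError("points are collinear or degenerate") from exc
    polygon = Polygon(pts[hull.vertices])
    if centroid_method == "area":
        c = polygon.centroid
        centroid = (c.x, c.y)
    elif centroid_method == "vertices":
        centroid = tuple(pts[hull.vertices].mean(axis=0))
    else:
        raise ValueError("centroid_method must be 'area' or 'vertices'")
    return polygon, centroid


def normalized_position(
    p: tuple[float, float],
    polygon: Polygon,
    centroid: tuple[float, float],
    *,
    neuron_id: str = "",
    tol: float = 1e-9,
) -> NeuronGeometry:
    """Angle and border-normalised distance of a point inside the polygon.

    The border point is the intersection of the ray centroid -> p with the
    polygon boundary; a point at the centroid has d_ratio 0 and an undefined
    (NaN) angle and is flagged.
    """
    px, py = float(p[0]), float(p[1])
    cx, cy = centroid
    scale = max(polygon.bounds[2] - polygon.bounds[0],
                polygon.bounds[3] - polygon.bounds[1], 1.0)
    if not polygon.buffer(tol * scale).covers(Point(px, py)):
        raise ValueError(f"point {p} lies outside the polygon")
    d = math.hypot(px - cx, py - cy)
    if d <= tol * scale:
        return NeuronGeometry(neuron_id, (px, py), float("nan"), 0.0, at_centroid=True)
    ux, uy = (px - cx) / d, (py - cy) / d
    far = (cx + 3.0 * scale * ux, cy + 3.0 * scale * uy)
    crossing = LineString([(cx, cy), far]).intersection(polygon.exterior)
    if crossing.is_empty:
        raise ValueError("ray from centroid does not reach the polygon boundary")
    # a convex polygon is crossed once, but the ray may graze a vertex; take
    # the farthest crossing along the ray
    candidates = (
        list(crossing.geoms) if hasattr(crossing, "geoms") else [crossing]
    )
    border_d = max(
        math.hypot(g.x - cx, g.y - cy) for g in candidates if isinstance(g, Point)
    )
    angle = math.atan2(py - cy, px - cx)
    return NeuronGeometry(neuron_id, (px, py), angle, d / border_d)


def angular_variance(angles: Sequence[float]) -> float:
    """Circular variance ``1 - R̄`` of a set of angles (radians), in [0, 1].

    0 when all angles coincide; 1 when the resultant vector cancels.
    """
    arr = np.asarray(angles, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("need at least one defined angle")
    resultant = abs(np.exp(1j * arr).mean())
    return float(1.0 - resultant)


def population_geometry(
    xy: Mapping[str, tuple[float, float]], centroid_method: str = "area"
) -> pd.DataFrame:
    """Per-neuron geometry table for a whole preparation.

    The hull is taken over all somata; returns columns
    neuron_id, x, y, angle, d_ratio, at_centroid.
    """
    polygon, centroid = hull_and_centroid(list(xy.values()), centroid_method)
    rows = []
    for neuron, p in sorted(xy.items()):
        g = normalized_position(p, polygon, centroid, neuron_id=neuron)
        rows.append(
            {
                "neuron_id": neuron,
                "x": p[0],
                "y": p[1],
                "angle": g.angle,
                "d_ratio": g.d_ratio,
                "at_centroid": g.at_centroid,
            }
        )
    return pd.DataFrame(rows)
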