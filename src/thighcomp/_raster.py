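"""Polygon rasterisation with a fixed, bit-stable containment convention.

Convention used everywhere in the package: pixel units, 0-based indices,
row-major arrays; a pixel belongs to a polygon iff its *center* (x=col,
y=row, both integers) is inside by the even-odd (ray-crossing) rule.
Polygons are implicitly closed (last vertex joins the first).  Edges are
treated half-open in y so a ray through a vertex is counted once.
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError


def polygon_mask(vertices, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers lie inside the polygon.

    Parameters
    ----------
    vertices : (n, 2) array-like
        Polygon vertices as (x, y) = (col, row) pixel coordinates.  A
        repeated final vertex is tolerated.
    shape : (rows, cols)
        Output mask shape.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise GeometryError(f"polygon vertices must be (n, 2); got {v.shape}")
    if not np.isfinite(v).all():
        raise GeometryError("polygon vertices must be finite")
    if len(v) > 1 and np.allclose(v[0], v[-1]):
        v = v[:-1]
    if len(v) < 3 or len(np.unique(v, axis=0)) < 3:
        raise GeometryError(f"polygon needs at least 3 distinct vertices; got {len(v)}")

    h, w = shape
    cols, rows = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    px = cols.ravel()
    py = rows.ravel()
    inside = np.zeros(px.shape, dtype=bool)

    x1, y1 = v[:, 0], v[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    for ex1, ey1, ex2, ey2 in zip(x1, y1, x2, y2):
        if ey1 == ey2:  # horizontal edge never crosses a half-open scanline
            continue
        crosses = (ey1 > py) != (ey2 > py)
        if not crosses.any():
            continue
        xi = ex1 + (py[crosses] - ey1) * (ex2 - ex1) / (ey2 - ey1)
        hit = np.zeros_like(crosses)
        hit[crosses] = px[crosses] < xi
        inside ^= hit
    return inside.reshape(h, w)


def disk_mask(center, radius: float, shape: tuple[int, int]) -> np.ndarray:
    """Pixels whose centers lie within ``radius`` of ``center`` (x, y)."""
    cx, cy = float(center[0]), float(center[1])
    if radius <= 0:
        raise GeometryError("disk radius must be positive")
    h, w = shape
    cols, rows = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    return (cols - cx) ** 2 + (rows - cy) ** 2 <= radius ** 2


def ellipse_polygon(center, semi_axes, n_vertices: int = 64) -> np.ndarray:
    """Polygonal approximation of an axis-aligned ellipse, (x, y) vertices."""
    cx, cy = center
    ax, ay = semi_axes
    if ax <= 0 or ay <= 0:
        raise GeometryError("ellipse semi-axes must be positive")
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    return np.column_stack([cx + ax * np.cos(t), cy + ay * np.sin(t)])
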