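"""Minimum-area enclosing ellipse (Loewner-John ellipse) in 2-D.

Used to locate the centre of the ellipse surrounding all marked pixels
of a drawing.  The solver runs Khachiyan's barycentric coordinate-
descent on the convex hull of the input, which is exact in the limit
and is iterated here to a tolerance far below pixel resolution.
Degenerate inputs (a single point, collinear points) fall back to the
midpoint of the extremes, which is the centre of the collapsed ellipse.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError

__all__ = ["min_enclosing_ellipse", "ellipse_centre"]


def _khachiyan(points: np.ndarray, tol: float, max_iter: int = 20000) -> tuple[np.ndarray, np.ndarray]:
    """Core iteration; returns (centre, shape matrix A) with the ellipse
    ``(x - c)^T A (x - c) <= 1``.

    Runs Frank-Wolfe steps on the dual D-optimal design problem until
    the duality gap ``max_j m_j / (d + 1) - 1`` falls below ``tol``.
    """
    n, d = points.shape
    q = np.column_stack([points, np.ones(n)])  # (n, d+1)
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        x = q.T @ (u[:, None] * q)
        m = np.einsum("ij,ij->i", q @ np.linalg.inv(x), q)
        j = int(np.argmax(m))
        if m[j] <= (d + 1.0) * (1.0 + tol):
            break
        step = (m[j] - d - 1.0) / ((d + 1.0) * (m[j] - 1.0))
        u *= 1.0 - step
        u[j] += step
    c = u @ points
    cov = points.T @ (u[:, None] * points) - np.outer(c, c)
    a = np.linalg.inv(cov) / d
    return c, a


def min_enclosing_ellipse(points: np.ndarray, tol: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """Centre and shape matrix of the minimum-area enclosing ellipse.

    Parameters
    ----------
    points
        ``(n, 2)`` coordinates.
    tol
        Relative duality-gap tolerance; the default puts the centre
        well within 0.1 mm for sheet-scale inputs.

    Returns
    -------
    centre, shape
        ``centre`` is the (x, y) ellipse centre.  ``shape`` is the
        positive-definite matrix A with all points satisfying
        ``(p - centre)^T A (p - centre) <= 1`` (up to tolerance), or
        ``None``-filled ``inf`` diagonal for degenerate inputs.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("points must be a non-empty (n, 2) array")
    uniq = np.unique(pts, axis=0)
    if len(uniq) == 1:
        return uniq[0].copy(), np.diag([np.inf, np.inf])
    # reduce to hull vertices; also detects collinear degeneracy
    try:
        hull = ConvexHull(uniq)
        verts = uniq[hull.vertices]
    except QhullError:
        # collinear: ellipse collapses to the segment between extremes
        direction = uniq[-1] - uniq[0]
        span = uniq @ direction
        lo, hi = uniq[np.argmin(span)], uniq[np.argmax(span)]
        return (lo + hi) / 2.0, np.diag([np.inf, np.inf])
    return _khachiyan(verts, tol)


def ellipse_centre(points: np.ndarray, tol: float = 1e-3) -> np.ndarray:
    """Centre of the minimum-area enclosing ellipse of ``points``."""
    return min_enclosing_ellipse(points, tol)[0]
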