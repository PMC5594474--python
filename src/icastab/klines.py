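"""Two-line (k-lines, k=2) clustering of stability-profile point clouds.

The analogue of 2-means with lines as centroids: points are assigned to
the nearest of two affine lines by orthogonal distance, each line is
refit by total least squares (orthogonal regression) on its points, and
the two steps alternate until the assignment stabilizes.  On overlaid
stability profiles the steeper line tracks the uniformly distributed
stabilities and the flatter line the mode of low-stability components;
their intersection is the MSTD estimate.

Lines are represented internally in point-direction form so vertical
initial lines (the ordinate axis) are expressible; the public
:class:`KLinesFit` reports slope/intercept pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Line", "KLinesFit", "fit_line_tls", "kline_cluster", "line_intersection"]

MAX_ITER = 200


@dataclass
class Line:
    """Affine line through ``point`` along unit ``direction``."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("line direction must be non-zero")
        self.direction = d / n
        self.point = np.asarray(self.point, dtype=float)

    def distance(self, points: np.ndarray) -> np.ndarray:
        """Orthogonal distances from 2-D points to the line."""
        v = np.atleast_2d(points) - self.point
        d = self.direction
        return np.abs(v[:, 0] * d[1] - v[:, 1] * d[0])

    @property
    def slope(self) -> float:
        dx, dy = self.direction
        return np.inf if dx == 0 else dy / dx

    @property
    def intercept(self) -> float:
        """y-intercept; infinite slope yields nan."""
        if self.direction[0] == 0:
            return np.nan
        return float(self.point[1] - self.slope * self.point[0])

    def transformed(self, scale: np.ndarray, offset: np.ndarray) -> "Line":
        """Map the line through the affine change of coordinates p -> p*scale + offset."""
        return Line(self.point * scale + offset, self.direction * scale)


def fit_line_tls(points: np.ndarray) -> Line:
    """Total-least-squares (orthogonal regression) line through 2-D points."""
    P = np.atleast_2d(np.asarray(points, dtype=float))
    if P.shape[0] < 2:
        raise ValueError("need at least 2 points to fit a line")
    centroid = P.mean(axis=0)
    _, _, vt = np.linalg.svd(P - centroid, full_matrices=False)
    return Line(centroid, vt[0])


@dataclass
class KLinesFit:
    """Result of the two-line clustering.

    ``line_steep`` / ``line_flat`` give (slope, intercept) of the fitted
    lines (steeper = larger absolute slope), ``assignments`` labels each
    point 0 for the steep line and 1 for the flat one, ``objective`` is
    the final sum of squared orthogonal distances.
    """

    line_steep: tuple[float, float]
    line_flat: tuple[float, float]
    assignments: np.ndarray
    iterations: int
    converged: bool
    objective: float
    lines: tuple[Line, Line] = None
    degenerate: bool = False


def _objective(points: np.ndarray, lines: list[Line], labels: np.ndarray) -> float:
    total = 0.0
    for j, line in enumerate(lines):
        pts = points[labels == j]
        if len(pts):
            total += float(np.sum(line.distance(pts) ** 2))
    return total


def _steepness(line: Line) -> float:
    dx, dy = line.direction
    return np.inf if dx == 0 else abs(dy / dx)


def kline_cluster(
    points: np.ndarray,
    init_lines: tuple[Line, Line] | None = None,
    max_iter: int = MAX_ITER,
    on_collinear: str = "error",
) -> KLinesFit:
    """Cluster 2-D points along two total-least-squares lines.

    Initial lines default to a near-vertical and a near-horizontal line
    through the data bounding box (the axis-matching initialization).
    Distance ties go to the steeper line.  A line that loses all its
    points is reinitialized through the two points farthest from the
    other line; if it collapses again the fit aborts.

    ``on_collinear`` controls the single-line degenerate case (all
    points on one line): ``"error"`` raises, ``"flag"`` returns a fit
    with ``degenerate=True``.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    if P.shape[0] < 4:
        raise ValueError("need at least 4 points for a two-line fit")
    single = fit_line_tls(P)
    if float(np.max(single.distance(P))) < 1e-12 * max(1.0, float(np.abs(P).max())):
        if on_collinear == "error":
            raise ValueError("all points lie on a single line")
        sl = (single.slope, single.intercept)
        return KLinesFit(
            line_steep=sl,
            line_flat=sl,
            assignments=np.zeros(len(P), dtype=int),
            iterations=0,
            converged=True,
            objective=0.0,
            lines=(single, single),
            degenerate=True,
        )
    if init_lines is None:
        lo, hi = P.min(axis=0), P.max(axis=0)
        mid = (lo + hi) / 2.0
        init_lines = (
            Line(np.array([lo[0], mid[1]]), np.array([0.0, 1.0])),  # near-vertical
            Line(np.array([mid[0], lo[1]]), np.array([1.0, 0.0])),  # near-horizontal
        )
    lines = list(init_lines)
    labels = None
    converged = False
    reinit_count = [0, 0]
    it = 0
    for it in range(1, max_iter + 1):
        D = np.column_stack([ln.distance(P) for ln in lines])
        # ties go to the steeper line
        steeper = 0 if _steepness(lines[0]) >= _steepness(lines[1]) else 1
        new_labels = np.where(
            D[:, 0] < D[:, 1], 0, np.where(D[:, 1] < D[:, 0], 1, steeper)
        )
        if labels is not None and np.array_equal(new_labels, labels):
            converged = True
            break
        labels = new_labels
        for j in (0, 1):
            pts = P[labels == j]
            if len(pts) < 2:
                reinit_count[j] += 1
                if reinit_count[j] > 2:
                    raise RuntimeError("a line repeatedly lost all its points")
                far = np.argsort(lines[1 - j].distance(P))[-2:]
                pts = P[far]
            lines[j] = fit_line_tls(pts)
    steep_idx = 0 if _steepness(lines[0]) >= _steepness(lines[1]) else 1
    flat_idx = 1 - steep_idx
    out_labels = np.where(labels == steep_idx, 0, 1)
    return KLinesFit(
        line_steep=(lines[steep_idx].slope, lines[steep_idx].intercept),
        line_flat=(lines[flat_idx].slope, lines[flat_idx].intercept),
        assignments=out_labels,
        iterations=it,
        converged=converged,
        objective=_objective(P, lines, labels),
        lines=(lines[steep_idx], lines[flat_idx]),
    )


def line_intersection(a: Line, b: Line) -> np.ndarray:
    """Intersection point of two lines; raises for (near-)parallel lines."""
    mat = np.column_stack([a.direction, -b.direction])
    det = float(np.linalg.det(mat))
    if abs(det) < 1e-12:
        raise ValueError("lines are parallel")
    t = np.linalg.solve(mat, b.point - a.point)
    return a.point + t[0] * a.direction
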