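"""Time-grid bookkeeping and trapezoidal functional inner products.

Curves are observed on a shared grid of J points spanning the normalized
time interval [0, 1].  Every projection in the package — learned bases onto
input trajectories, penalty integrals — reduces to the trapezoidal rule on
this grid, so the quadrature weights live here and are computed once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeGrid", "make_time_grid", "trapezoid_inner_product"]


@dataclass(frozen=True)
class TimeGrid:
    """An ordered grid on [0, 1].

    Attributes
    ----------
    points
        Strictly increasing array of length ``J`` with ``points[0] == 0``
        and ``points[-1] == 1``.
    """

    points: np.ndarray
    _weights: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 1 or pts.size < 2:
            raise ValueError("a time grid needs at least two points")
        if not (pts[0] == 0.0 and pts[-1] == 1.0):
            raise ValueError("grid must start at 0 and end at 1")
        if np.any(np.diff(pts) <= 0):
            raise ValueError("grid points must be strictly increasing")
        object.__setattr__(self, "points", pts)
        # trapezoid quadrature weights: w_j = (t_{j+1} - t_{j-1}) / 2 at
        # interior points, half-intervals at the ends; valid for non-uniform
        # spacing even though the package only ever builds uniform grids.
        dt = np.diff(pts)
        w = np.zeros_like(pts)
        w[:-1] += dt / 2.0
        w[1:] += dt / 2.0
        object.__setattr__(self, "_weights", w)

    @property
    def J(self) -> int:
        return self.points.size

    @property
    def weights(self) -> np.ndarray:
        """Trapezoid quadrature weights (length J, sums to 1)."""
        return self._weights


def make_time_grid(J: int) -> TimeGrid:
    """Uniform grid of ``J`` points on [0, 1], endpoints included."""
    if J < 2:
        raise ValueError(f"J must be >= 2, got {J}")
    return TimeGrid(np.linspace(0.0, 1.0, J))


def trapezoid_inner_product(curve_a, curve_b, grid: TimeGrid) -> float:
    """Trapezoidal approximation of the L2 inner product on [0, 1].

    Computes ``sum_j w_j a(t_j) b(t_j)`` with the grid's quadrature weights;
    bilinear and symmetric, with left-to-right summation order fixed for
    run-to-run reproducibility.
    """
    a = np.asarray(curve_a, dtype=np.float64)
    b = np.asarray(curve_b, dtype=np.float64)
    if a.shape != (grid.J,) or b.shape != (grid.J,):
        raise ValueError(
            f"curves must have shape ({grid.J},), got {a.shape} and {b.shape}"
        )
    return float(np.add.reduce(a * b * grid.weights))
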