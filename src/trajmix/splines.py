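"""Quadratic B-spline basis for group mean growth curves.

Group mean curves live in a low-dimensional piecewise-quadratic space: a
degree-2 B-spline with a single internal knot at the pooled median observed
age, boundary knots at the observed age range.  That gives a 4-dimensional
basis — flexible enough for "stable then rising" shapes over ages 2-9 while
keeping the mixture parsimonious.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineBasis", "build_spline_basis"]


@dataclass(frozen=True)
class SplineBasis:
    degree: int
    internal_knots: tuple[float, ...]
    boundary: tuple[float, float]

    @property
    def dimension(self) -> int:
        return self.degree + 1 + len(self.internal_knots)

    @property
    def knot_vector(self) -> np.ndarray:
        lo, hi = self.boundary
        return np.concatenate(
            [
                np.repeat(lo, self.degree + 1),
                np.asarray(self.internal_knots, dtype=float),
                np.repeat(hi, self.degree + 1),
            ]
        )

    def design(self, ages) -> np.ndarray:
        """Evaluate the basis at ``ages``; rows sum to 1 inside the boundary."""
        x = np.atleast_1d(np.asarray(ages, dtype=float))
        lo, hi = self.boundary
        if np.any(x < lo) or np.any(x > hi):
            raise ValueError(
                f"ages outside the boundary knots [{lo}, {hi}]; "
                "refit the basis on the pooled observed ages"
            )
        M = BSpline.design_matrix(x, self.knot_vector, self.degree, extrapolate=False)
        return np.asarray(M.todense())

    def curve(self, coef: np.ndarray, ages) -> np.ndarray:
        """Mean curve X(age) @ coef."""
        return self.design(ages) @ np.asarray(coef, dtype=float)


def build_spline_basis(ages, degree: int = 2, n_internal: int = 1) -> SplineBasis:
    """Basis from pooled observed ages: internal knot(s) at quantiles, boundary at range.

    With the defaults (quadratic, one internal knot at the median) the basis
    dimension is 4.
    """
    x = np.asarray(ages, dtype=float)
    distinct = np.unique(x)
    if distinct.size < 3:
        raise ValueError(f"need >= 3 distinct ages to build a basis, got {distinct.size}")
    qs = np.linspace(0, 1, n_internal + 2)[1:-1]
    internal = tuple(float(np.quantile(x, q)) for q in qs)
    lo, hi = float(distinct[0]), float(distinct[-1])
    if any(not (lo < k < hi) for k in internal):
        raise ValueError("internal knot coincides with a boundary knot")
    return SplineBasis(degree=degree, internal_knots=internal, boundary=(lo, hi))
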