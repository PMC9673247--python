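"""Natural cubic spline basis for developmental-stage coordinates.

Time-course differential expression encodes the stage coordinate through a
natural cubic spline basis rather than as unordered categories (which would
ignore temporal ordering and inflate the number of tested contrasts) or as a
single linear term (which cannot represent transient up/down-regulation).

The basis is the truncated-power natural-spline construction: with sorted
knots ``xi_1 < ... < xi_K`` (boundary knots at the extreme times, interior
knots at quantiles of the distinct times), define

    d_k(x) = [ (x - xi_k)_+^3 - (x - xi_K)_+^3 ] / (xi_K - xi_k)

and take the ``df`` basis functions ``x`` and ``d_k(x) - d_{K-1}(x)`` for
``k = 1..K-2`` (the constant function is left to the design intercept).
Every basis function has zero second and third derivative at and beyond the
boundary knots, so extrapolation is affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplineBasis", "natural_spline_basis"]


@dataclass(frozen=True)
class SplineBasis:
    """A natural cubic spline basis evaluated at a fixed set of times.

    Attributes
    ----------
    df : int
        Number of basis columns (excluding the intercept).
    interior_knots : ndarray
        Sorted interior knots (empty for ``df == 1``).
    boundary_knots : tuple of float
        ``(min, max)`` of the construction times.
    times : ndarray
        The distinct times the basis was built from.
    basis_values : ndarray of shape (len(times), df)
        The basis evaluated at ``times``.
    """

    df: int
    interior_knots: np.ndarray
    boundary_knots: tuple[float, float]
    times: np.ndarray
    basis_values: np.ndarray = field(repr=False)

    @property
    def knots(self) -> np.ndarray:
        """All knots, boundary included, sorted ascending."""
        return np.concatenate(
            ([self.boundary_knots[0]], self.interior_knots, [self.boundary_knots[1]])
        )

    def evaluate(self, times) -> np.ndarray:
        """Evaluate the basis at arbitrary query times.

        Extrapolation beyond the boundary knots is affine (natural-spline
        boundary condition); repeated query times yield identical rows.
        """
        x = np.asarray(times, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("query times must be finite")
        return _natural_spline_design(x, self.knots)


def _truncated_cubic(x: np.ndarray, knot: float) -> np.ndarray:
    return np.maximum(x - knot, 0.0) ** 3


def _natural_spline_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Truncated-power natural spline basis on ``knots``; K knots -> K-1 columns."""
    K = len(knots)
    cols = [x]
    if K > 2:
        xi_K = knots[-1]

        def d(k: int) -> np.ndarray:
            return (_truncated_cubic(x, knots[k]) - _truncated_cubic(x, xi_K)) / (
                xi_K - knots[k]
            )

        d_last = d(K - 2)  # d_{K-1} in 1-based notation
        for k in range(K - 2):
            cols.append(d(k) - d_last)
    return np.column_stack(cols)


def natural_spline_basis(times, df: int) -> SplineBasis:
    """Build a natural cubic spline basis from distinct stage coordinates.

    Parameters
    ----------
    times : sequence of float
        Distinct, finite time coordinates, sorted ascending.
    df : int
        Basis dimension; must satisfy ``1 <= df <= len(times) - 1``.
        ``df = 1`` degenerates to the linear term.

    Returns
    -------
    SplineBasis
        Boundary knots at ``(min(times), max(times))``; ``df - 1`` interior
        knots at evenly spaced quantiles of ``times``.

    Raises
    ------
    ValueError
        If ``times`` are not distinct/sorted/finite or ``df`` is out of range.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("need at least two distinct times")
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing (distinct and sorted)")
    n = len(t)
    if not (1 <= df <= n - 1):
        raise ValueError(
            f"df={df} out of range: must satisfy 1 <= df <= (distinct times - 1) = {n - 1}"
        )
    boundary = (float(t[0]), float(t[-1]))
    if df == 1:
        interior = np.empty(0)
    else:
        probs = np.arange(1, df) / df
        interior = np.quantile(t, probs)
    knots = np.concatenate(([boundary[0]], interior, [boundary[1]]))
    values = _natural_spline_design(t, knots)
    return SplineBasis(
        df=df,
        interior_knots=interior,
        boundary_knots=boundary,
        times=t,
        basis_values=values,
    )
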