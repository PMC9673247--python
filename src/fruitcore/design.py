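"""Design matrices for the nested spline models.

Four model kinds are supported, forming the nesting used throughout:

- ``noise``            — intercept only (no expression change over time);
- ``spline``           — intercept + spline(time): one shared trajectory,
  blind to species and fruit type;
- ``spline_by_group``  — adds group main effects and group:spline
  interactions for a grouping variable (``fruit_type`` or ``species``),
  giving each group its own trajectory.

``spline_by_species`` is ``spline_by_group`` with ``group_field='species'``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .splines import SplineBasis

__all__ = ["DesignMatrix", "build_design", "DESIGN_KINDS"]

logger = logging.getLogger(__name__)

DESIGN_KINDS = ("noise", "spline", "spline_by_group", "spline_by_species")


@dataclass(frozen=True)
class DesignMatrix:
    """A labelled samples-by-coefficients model matrix."""

    kind: str
    columns: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column labels inconsistent with matrix width")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_params(self) -> int:
        return self.values.shape[1]

    def is_nested_in(self, full: "DesignMatrix", tol: float = 1e-8) -> bool:
        """True if this matrix's column space is contained in ``full``'s."""
        X = full.values
        proj, *_ = np.linalg.lstsq(X, self.values, rcond=None)
        resid = self.values - X @ proj
        scale = max(1.0, np.abs(self.values).max())
        return bool(np.abs(resid).max() <= tol * scale)


def _check_full_rank(values: np.ndarray, columns: list[str], kind: str) -> None:
    rank = np.linalg.matrix_rank(values)
    if rank < values.shape[1]:
        # name columns involved in the deficiency for the error message
        _, r = np.linalg.qr(values)
        diag = np.abs(np.diag(r))
        bad = [columns[i] for i in np.nonzero(diag < 1e-10 * max(diag.max(), 1.0))[0]]
        raise ValueError(
            f"design matrix (kind={kind}) is rank deficient "
            f"(rank {rank} < {values.shape[1]}); offending columns: {bad or columns}"
        )


def build_design(
    samples: pd.DataFrame,
    basis: SplineBasis | None,
    kind: str,
    group_field: str | None = None,
) -> DesignMatrix:
    """Build the model matrix for one model kind.

    Parameters
    ----------
    samples : DataFrame
        Validated sample metadata (needs ``time``; plus ``group_field`` for
        grouped kinds).
    basis : SplineBasis or None
        Spline basis; evaluated at each sample's time.  May be ``None`` only
        for ``kind='noise'``.
    kind : str
        One of ``noise``, ``spline``, ``spline_by_group``,
        ``spline_by_species``.
    group_field : str, optional
        ``'fruit_type'`` or ``'species'``; required for grouped kinds
        (``spline_by_species`` forces ``'species'``).

    Notes
    -----
    Group levels are sorted; the first level is the reference absorbed into
    the intercept, the remaining ``g - 1`` levels get indicator and
    indicator:spline interaction columns.  Sample times outside the basis'
    boundary knots are allowed (affine extrapolation) but logged.
    """
    if kind not in DESIGN_KINDS:
        raise ValueError(f"unknown design kind {kind!r}; expected one of {DESIGN_KINDS}")
    n = len(samples)
    if kind == "noise":
        return DesignMatrix("noise", ("intercept",), np.ones((n, 1)))

    if basis is None:
        raise ValueError("a SplineBasis is required for spline designs")
    times = samples["time"].to_numpy(dtype=float)
    lo, hi = basis.boundary_knots
    if times.min() < lo or times.max() > hi:
        logger.warning(
            "sample times extend beyond spline boundary knots [%g, %g]; "
            "extrapolating affinely",
            lo,
            hi,
        )
    S = basis.evaluate(times)
    spline_cols = [f"spline_{k + 1}" for k in range(basis.df)]

    if kind == "spline":
        values = np.column_stack([np.ones(n), S])
        columns = ["intercept", *spline_cols]
        _check_full_rank(values, columns, kind)
        return DesignMatrix(kind, tuple(columns), values)

    if kind == "spline_by_species":
        group_field = "species"
    if group_field not in ("fruit_type", "species"):
        raise ValueError("group_field must be 'fruit_type' or 'species' for grouped designs")
    groups = samples[group_field].astype(str).to_numpy()
    levels = sorted(set(groups))
    if len(levels) < 2:
        raise ValueError(
            f"grouped design needs >= 2 levels of {group_field!r}; got {levels}"
        )
    blocks = [np.ones((n, 1)), S]
    columns = ["intercept", *spline_cols]
    for lev in levels[1:]:
        ind = (groups == lev).astype(float)
        blocks.append(ind[:, None])
        columns.append(f"{group_field}_{lev}")
    for lev in levels[1:]:
        ind = (groups == lev).astype(float)
        blocks.append(ind[:, None] * S)
        columns.extend(f"{group_field}_{lev}:spline_{k + 1}" for k in range(basis.df))
    values = np.column_stack(blocks)
    _check_full_rank(values, columns, kind)
    return DesignMatrix(kind, tuple(columns), values)
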