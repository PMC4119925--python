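"""P-spline building blocks: B-spline bases on equidistant knots and
difference penalties (Eilers–Marx style)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineBasisSpec", "build_bspline_basis", "build_difference_penalty"]


@dataclass(frozen=True)
class SplineBasisSpec:
    """Configuration of one penalized smooth.

    num_basis
        Number of B-spline basis functions (columns), default 8.
    degree
        Spline degree, default 3 (cubic).
    penalty_order
        Order of the difference penalty on adjacent coefficients,
        default 2 (second differences, shrinking toward a straight line).
    """

    num_basis: int = 8
    degree: int = 3
    penalty_order: int = 2

    def __post_init__(self) -> None:
        if self.degree < 0:
            raise ValueError("degree must be >= 0")
        if self.num_basis < self.degree + 1:
            raise ValueError("num_basis must be >= degree + 1")
        # penalty_order 0 means an unpenalized basis (degenerate but legal)
        if not (0 <= self.penalty_order < self.num_basis):
            raise ValueError("penalty_order must satisfy 0 <= order < num_basis")


def _knots(lo: float, hi: float, num_basis: int, degree: int) -> np.ndarray:
    """Equidistant knot vector with ``degree`` padding knots on each side."""
    n_seg = num_basis - degree
    h = (hi - lo) / n_seg
    interior = np.linspace(lo, hi, n_seg + 1)  # endpoints exact
    left = lo - h * np.arange(degree, 0, -1)
    right = hi + h * np.arange(1, degree + 1)
    return np.concatenate([left, interior, right])


def build_bspline_basis(
    x: np.ndarray, spec: SplineBasisSpec
) -> tuple[np.ndarray, np.ndarray, SplineBasisSpec]:
    """Evaluate a B-spline basis on equidistant knots covering ``x``.

    Returns the (n, num_basis) design block, the full knot vector, and the
    spec actually used: when ``x`` has fewer distinct values than basis
    functions, ``num_basis`` is reduced to that number (never below
    ``degree + 1``) with a warning, so the basis stays estimable.

    Rows sum to 1 (B-spline partition of unity) for every point in
    ``[min(x), max(x)]``.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise ValueError("x must be non-empty and finite")
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise ValueError("x must span a non-degenerate range")
    n_distinct = len(np.unique(x))
    if n_distinct < spec.num_basis:
        reduced = max(n_distinct, spec.degree + 1)
        order = max(min(spec.penalty_order, reduced - 1), 0)
        warnings.warn(
            f"only {n_distinct} distinct x values; reducing num_basis "
            f"{spec.num_basis} -> {reduced}",
            stacklevel=2,
        )
        spec = SplineBasisSpec(reduced, spec.degree, order)
    t = _knots(lo, hi, spec.num_basis, spec.degree)
    B = BSpline.design_matrix(x, t, spec.degree, extrapolate=False).toarray()
    return B, t, spec


def build_difference_penalty(num_basis: int, order: int) -> np.ndarray:
    """Penalty matrix DᵀD for order-th differences of adjacent coefficients.

    Positive semidefinite; its null space is spanned by polynomial
    sequences of degree < ``order`` in the coefficient index, so heavy
    smoothing shrinks the fitted curve toward such a polynomial.
    """
    if not (0 < order < num_basis):
        raise ValueError("order must satisfy 0 < order < num_basis")
    D = np.diff(np.eye(num_basis), n=order, axis=0)
    return D.T @ D
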