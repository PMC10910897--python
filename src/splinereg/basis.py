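"""Design matrices for the five model families.

All bases are built from truncated power terms ``(x - k)+ = max(x - k, 0)``.
A linear spline (LSP) adds one ``(x - k)+`` column per knot to the linear
predictor; because each term is continuous, the fitted curve is piecewise
linear with no jumps at the knots. The restricted cubic spline (RCS) cubes
the truncated terms and combines them so the curve is linear before the
first and after the last knot; with 3 knots that leaves a single spline
column beyond the intercept and ``x``:

    s(x) = [ (x-k1)+^3
             - (x-k2)+^3 (k3-k1)/(k3-k2)
             + (x-k3)+^3 (k2-k1)/(k3-k2) ] / (k3-k1)^2

The (k3-k1)^2 divisor keeps the spline coefficient on a scale comparable to
the linear slope; the equivalent unnormalised truncated-cubic "interval
form" (one cubed term per knot) is provided for evaluating converted
per-interval coefficients, never for fitting.

Interval boundary convention: lower intervals include their right boundary,
i.e. the spline term for knot k is exactly zero whenever x <= k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .knots import KnotSet, QuartileBounds

__all__ = [
    "BasisMatrix",
    "UnsupportedKnotCountError",
    "truncate_pos",
    "linear_design",
    "quadratic_design",
    "categorical_design",
    "lsp_design",
    "rcs_design",
    "rcs_truncated_design",
    "design_for",
    "FAMILIES",
]

FAMILIES = ("linear", "quadratic", "categorical", "lsp", "rcs", "rcs_truncated")


class UnsupportedKnotCountError(ValueError):
    """Raised for restricted-cubic bases with a knot count other than 3."""


def _fmt_knot(k: float) -> str:
    return format(k, "g")


@dataclass(frozen=True)
class BasisMatrix:
    """A labeled design matrix for one model family.

    ``matrix`` has one row per observation; the first column is the constant
    intercept. Column names are stable strings (``"intercept"``, ``"x"``,
    ``"x_minus_330_pos"``, ``"rcs1"``, ...) so downstream reports are
    reproducible bit-for-bit.
    """

    matrix: np.ndarray
    names: tuple[str, ...]
    family: str
    knots: KnotSet | None = None
    bounds: QuartileBounds | None = None

    def __post_init__(self) -> None:
        m = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        object.__setattr__(self, "matrix", m)
        if m.shape[1] != len(self.names):
            raise ValueError("one name per design column is required")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def truncate_pos(x, k):
    """Truncated power term ``(x - k)+ = max(x - k, 0)``.

    Zero whenever ``x - k <= 0``, so the lower interval includes its right
    boundary. Works elementwise on arrays.
    """
    return np.maximum(np.asarray(x, dtype=float) - k, 0.0)


def _as_column_input(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty exposure vector")
    return x


def linear_design(x) -> BasisMatrix:
    """Design for simple linear regression: columns [1, x]."""
    x = _as_column_input(x)
    return BasisMatrix(
        matrix=np.column_stack([np.ones_like(x), x]),
        names=("intercept", "x"),
        family="linear",
    )


def quadratic_design(x) -> BasisMatrix:
    """Design for quadratic regression: columns [1, x, x^2]."""
    x = _as_column_input(x)
    return BasisMatrix(
        matrix=np.column_stack([np.ones_like(x), x, x * x]),
        names=("intercept", "x", "x2"),
        family="quadratic",
    )


def categorical_design(x, bounds: QuartileBounds) -> BasisMatrix:
    """Quartile-dummy design: columns [1, I(q1<x<=q2), I(q2<x<=q3), I(x>q3)].

    The lowest quartile is the reference category (all indicators zero), so
    the intercept estimates its mean outcome and each coefficient the mean
    difference from that reference. Boundary convention matches the spline
    bases: left-open, right-closed.
    """
    x = _as_column_input(x)
    q1, q2, q3 = bounds.cuts
    cols = [
        np.ones_like(x),
        ((x > q1) & (x <= q2)).astype(float),
        ((x > q2) & (x <= q3)).astype(float),
        (x > q3).astype(float),
    ]
    return BasisMatrix(
        matrix=np.column_stack(cols),
        names=("intercept", "quartile2", "quartile3", "quartile4"),
        family="categorical",
        bounds=bounds,
    )


def _warn_tail_knots(x: np.ndarray, knots: KnotSet) -> None:
    lo, hi = x.min(), x.max()
    outside = [k for k in knots if k < lo or k > hi]
    if outside:
        warnings.warn(
            f"knots {outside} lie outside the observed exposure range "
            f"[{lo:g}, {hi:g}]; the corresponding tail interval has no data",
            stacklevel=3,
        )


def lsp_design(x, knots: KnotSet) -> BasisMatrix:
    """Linear-spline design: columns [1, x, (x-k1)+, ..., (x-kK)+]."""
    x = _as_column_input(x)
    _warn_tail_knots(x, knots)
    cols = [np.ones_like(x), x]
    names = ["intercept", "x"]
    for k in knots:
        cols.append(truncate_pos(x, k))
        names.append(f"x_minus_{_fmt_knot(k)}_pos")
    return BasisMatrix(
        matrix=np.column_stack(cols), names=tuple(names),
        family="lsp", knots=knots,
    )


def _require_three_knots(knots: KnotSet) -> tuple[float, float, float]:
    if len(knots) != 3:
        raise UnsupportedKnotCountError(
            f"restricted cubic splines are implemented for exactly 3 knots, "
            f"got {len(knots)}"
        )
    return knots[0], knots[1], knots[2]


def rcs_basis_function(x, knots: KnotSet) -> np.ndarray:
    """The single 3-knot restricted-cubic spline column s(x) (see module docs)."""
    k1, k2, k3 = _require_three_knots(knots)
    s = (
        truncate_pos(x, k1) ** 3
        - truncate_pos(x, k2) ** 3 * (k3 - k1) / (k3 - k2)
        + truncate_pos(x, k3) ** 3 * (k2 - k1) / (k3 - k2)
    )
    return s / (k3 - k1) ** 2


def rcs_design(x, knots: KnotSet) -> BasisMatrix:
    """Restricted-cubic-spline design for 3 knots: columns [1, x, s(x)].

    The fitted function b0 + b1*x + b2*s(x) is linear for x <= k1 and for
    x >= k3 and twice continuously differentiable everywhere.
    """
    x = _as_column_input(x)
    _require_three_knots(knots)
    _warn_tail_knots(x, knots)
    return BasisMatrix(
        matrix=np.column_stack([np.ones_like(x), x, rcs_basis_function(x, knots)]),
        names=("intercept", "x", "rcs1"),
        family="rcs",
        knots=knots,
    )


def rcs_truncated_design(x, knots: KnotSet) -> BasisMatrix:
    """Truncated-cubic interval form: columns [1, x, (x-k1)+^3, ..., (x-k3)+^3].

    Used only to evaluate the interval form with coefficients converted from
    the restricted fit; fitting it unrestricted would lose the tail-linearity
    constraints.
    """
    x = _as_column_input(x)
    _require_three_knots(knots)
    cols = [np.ones_like(x), x]
    names = ["intercept", "x"]
    for k in knots:
        cols.append(truncate_pos(x, k) ** 3)
        names.append(f"x_minus_{_fmt_knot(k)}_pos3")
    return BasisMatrix(
        matrix=np.column_stack(cols), names=tuple(names),
        family="rcs_truncated", knots=knots,
    )


def design_for(
    family: str,
    x,
    knots: KnotSet | None = None,
    bounds: QuartileBounds | None = None,
) -> BasisMatrix:
    """Dispatch to the design constructor for ``family``."""
    if family == "linear":
        return linear_design(x)
    if family == "quadratic":
        return quadratic_design(x)
    if family == "categorical":
        if bounds is None:
            raise ValueError("categorical design requires quartile bounds")
        return categorical_design(x, bounds)
    if family in ("lsp", "rcs", "rcs_truncated"):
        if knots is None:
            raise ValueError(f"{family} design requires knots")
        ctor = {
            "lsp": lsp_design,
            "rcs": rcs_design,
            "rcs_truncated": rcs_truncated_design,
        }[family]
        return ctor(x, knots)
    raise ValueError(f"unknown model family {family!r}")
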