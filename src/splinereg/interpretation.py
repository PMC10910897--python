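"""Turning fitted coefficients into interpretable quantities.

For a linear spline, the slope in interval j is the cumulative sum of the
linear coefficient and the first j spline coefficients — each spline
coefficient is the *change* in slope at its knot. For the 3-knot restricted
cubic spline, the single spline coefficient b (on the normalised basis)
converts to three per-interval truncated-cubic coefficients:

    b2 = b / (k3 - k1)^2
    b3 = b2 * (k1 - k3) / (k3 - k2)
    b4 = b2 * (k1 - k2) / (k2 - k3)

which satisfy b2 + b3 + b4 = 0 and b2*k1 + b3*k2 + b4*k3 = 0 — exactly the
conditions for the curve to be linear beyond the last knot.

Exposure contrasts (the predicted outcome difference between two exposure
values) are the recommended summary for any model whose effect varies with
exposure; within one linear-spline interval a one-unit contrast equals the
interval slope exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .basis import design_for
from .fitting import FittedModel
from .knots import KnotSet

__all__ = [
    "IntervalCoefficients",
    "ContrastEffect",
    "PredictionCurve",
    "lsp_interval_slopes",
    "rcs_interval_coeffs",
    "predict",
    "contrast",
    "check_tail_linearity",
]


@dataclass(frozen=True)
class IntervalCoefficients:
    """Per-interval coefficients with the intervals they apply to.

    ``intervals`` are (lower, upper] pairs in exposure units (open ends are
    ``-inf``/``+inf``). ``kind`` is ``"slope"`` for linear splines (outcome
    units per exposure unit) or ``"cubic"`` for the truncated-cubic interval
    form of an RCS. ``derivation`` records the cumulative-sum terms used.
    """

    intervals: tuple[tuple[float, float], ...]
    values: tuple[float, ...]
    kind: str
    derivation: tuple[str, ...]
    se: tuple[float, ...] | None = None
    ci: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if len(self.intervals) != len(self.values):
            raise ValueError("one value per interval is required")


@dataclass(frozen=True)
class ContrastEffect:
    """Predicted outcome difference between two exposure values.

    ``difference`` is predict(x1) - predict(x0) (signed); ``decrease`` is its
    negation, the way "the outcome decreased by ..." is usually reported.
    """

    x0: float
    x1: float
    difference: float
    ci: tuple[float, float] | None = None

    @property
    def decrease(self) -> float:
        return -self.difference


@dataclass(frozen=True)
class PredictionCurve:
    """Fitted values with pointwise confidence limits on an exposure grid."""

    x: np.ndarray
    fit: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    extrapolated: np.ndarray  # True where x falls outside the knot/bound range

    def __post_init__(self) -> None:
        for name in ("x", "fit", "ci_low", "ci_high"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (
            np.all(self.ci_low <= self.fit + 1e-12)
            and np.all(self.fit <= self.ci_high + 1e-12)
        ):
            raise ValueError("confidence limits must bracket the fitted values")


def lsp_interval_slopes(
    model: FittedModel, knots: KnotSet | None = None, level: float | None = None
) -> IntervalCoefficients:
    """Per-interval slopes of a linear spline model.

    Interval j's slope is beta1 plus the sum of the first j spline
    coefficients; intervals are delimited by the knots with the lower
    interval including its right boundary. When ``level`` is given and the
    model carries a covariance, each slope gets a Wald standard error and
    t confidence interval (the slope is a linear combination c'beta).
    """
    if model.family != "lsp":
        raise ValueError(f"expected an lsp model, got family {model.family!r}")
    knots = knots if knots is not None else model.knots
    if knots is None:
        raise ValueError("knots are required to delimit the intervals")
    k = len(knots)
    if model.params.size != k + 2:
        raise ValueError(
            f"a {k}-knot linear spline has {k + 2} coefficients, "
            f"model has {model.params.size}"
        )

    slopes, derivations = [], []
    for j in range(k + 1):
        # contrast vector selecting beta1 and the first j spline coefficients
        c = np.zeros(model.params.size)
        c[1 : 2 + j] = 1.0
        slopes.append(float(c @ model.params))
        terms = " + ".join(model.names[1 : 2 + j])
        derivations.append(terms)

    edges = (-np.inf, *knots.values, np.inf)
    intervals = tuple(zip(edges[:-1], edges[1:]))

    se = ci = None
    if level is not None:
        if model.cov is None or model.df_resid is None:
            raise ValueError("model carries no covariance; intervals unavailable")
        tcrit = stats.t.ppf(0.5 + level / 2.0, df=model.df_resid)
        ses, cis = [], []
        for j, slope in enumerate(slopes):
            c = np.zeros(model.params.size)
            c[1 : 2 + j] = 1.0
            s = float(np.sqrt(c @ model.cov @ c))
            ses.append(s)
            cis.append((slope - tcrit * s, slope + tcrit * s))
        se, ci = tuple(ses), tuple(cis)

    return IntervalCoefficients(
        intervals=intervals,
        values=tuple(slopes),
        kind="slope",
        derivation=tuple(derivations),
        se=se,
        ci=ci,
    )


def rcs_interval_coeffs(
    beta2_dagger: float, knots: KnotSet
) -> tuple[float, float, float]:
    """Convert the restricted-basis spline coefficient to interval form.

    Returns the three truncated-cubic coefficients (b2, b3, b4) that apply
    to ``(x-k1)+^3``, ``(x-k2)+^3`` and ``(x-k3)+^3`` respectively; the
    triple satisfies the tail-linearity identities sum(b) = 0 and
    sum(b*k) = 0 to machine tolerance.
    """
    if len(knots) != 3:
        from .basis import UnsupportedKnotCountError

        raise UnsupportedKnotCountError(
            f"interval-coefficient conversion needs exactly 3 knots, got {len(knots)}"
        )
    k1, k2, k3 = knots.values
    b2 = beta2_dagger / (k3 - k1) ** 2
    b3 = b2 * (k1 - k3) / (k3 - k2)
    b4 = b2 * (k1 - k2) / (k2 - k3)
    return (b2, b3, b4)


def check_tail_linearity(
    coeffs, knots: KnotSet
) -> tuple[float, float]:
    """Residuals of the right-tail linearity conditions for cubic coefficients.

    For the interval form to be linear beyond the last knot, the cubic
    coefficients must satisfy sum(b) = 0 and sum(b*k) = 0 (the cubic and
    quadratic terms of the right-tail polynomial must cancel). Returns the
    two residuals; a conforming conversion yields both ~ 0.
    """
    b = np.asarray(coeffs, dtype=float)
    k = np.asarray(knots.values, dtype=float)
    if b.size != k.size:
        raise ValueError("one cubic coefficient per knot is required")
    return (float(b.sum()), float(b @ k))


def _evaluate(model: FittedModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Design rows and fitted values for a grid under the model's own basis."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tail-knot warnings on small grids
        design = design_for(model.family, x, knots=model.knots, bounds=model.bounds)
    return design.matrix, design.matrix @ model.params


def _extrapolation_mask(model: FittedModel, x: np.ndarray) -> np.ndarray:
    if model.knots is not None:
        lo, hi = model.knots[0], model.knots[len(model.knots) - 1]
    elif model.bounds is not None:
        lo, hi = model.bounds.min, model.bounds.max
    else:
        return np.zeros(x.size, dtype=bool)
    return (x < lo) | (x > hi)


def predict(model: FittedModel, x, level: float = 0.95) -> PredictionCurve:
    """Fitted values with pointwise Wald confidence limits on a grid.

    Grid points beyond the model's knot (or quartile) range are flagged as
    extrapolated rather than rejected. Models built from published
    coefficients carry no covariance; their bands collapse onto the fit.
    """
    x = np.asarray(x, dtype=float).ravel()
    rows, yhat = _evaluate(model, x)
    if model.cov is not None and model.df_resid is not None:
        var = np.einsum("ij,jk,ik->i", rows, model.cov, rows)
        half = stats.t.ppf(0.5 + level / 2.0, df=model.df_resid) * np.sqrt(var)
    else:
        half = np.zeros_like(yhat)
    return PredictionCurve(
        x=x,
        fit=yhat,
        ci_low=yhat - half,
        ci_high=yhat + half,
        extrapolated=_extrapolation_mask(model, x),
    )


def contrast(
    model: FittedModel, x0: float, x1: float, level: float | None = None
) -> ContrastEffect:
    """Predicted outcome difference when the exposure moves from x0 to x1.

    The difference is antisymmetric in (x0, x1). For linear and linear-spline
    models with both points in one interval it equals the interval slope
    times (x1 - x0). With ``level`` set and a covariance available, a Wald t
    interval for the difference (a linear combination of coefficients) is
    attached.
    """
    rows, yhat = _evaluate(model, np.array([float(x0), float(x1)]))
    diff = float(yhat[1] - yhat[0])
    ci = None
    if level is not None:
        if model.cov is None or model.df_resid is None:
            raise ValueError("model carries no covariance; intervals unavailable")
        c = rows[1] - rows[0]
        se = float(np.sqrt(c @ model.cov @ c))
        tcrit = stats.t.ppf(0.5 + level / 2.0, df=model.df_resid)
        ci = (diff - tcrit * se, diff + tcrit * se)
    return ContrastEffect(x0=float(x0), x1=float(x1), difference=diff, ci=ci)
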