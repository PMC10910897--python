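"""Ordinary least squares for spline design matrices.

Truncated-cubic columns on mm-scale exposures reach ~1e9, so the solver
scales each non-intercept column to unit Euclidean norm, solves the scaled
problem by QR (via ``numpy.linalg.lstsq``), and undoes the scaling on
output; reported coefficients and covariances are therefore on the original
data scale. Normal equations are never formed for estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats

from .basis import BasisMatrix, design_for
from .knots import KnotSet, QuartileBounds

__all__ = [
    "FittedModel",
    "SingularDesignError",
    "InsufficientDataError",
    "fit",
    "adjusted_r2",
    "confint",
    "bootstrap_confint",
]


class SingularDesignError(ValueError):
    """Raised when the design matrix is rank-deficient."""


class InsufficientDataError(ValueError):
    """Raised when there are too few observations to estimate the model."""


@dataclass(frozen=True)
class FittedModel:
    """An OLS fit (or an externally supplied coefficient set) for one family.

    ``params`` holds the intercept followed by the slope coefficients, on
    the original data scale and in design-column order. ``cov`` is the
    classical OLS coefficient covariance, or ``None`` for models built from
    published coefficients (no uncertainty information).
    """

    family: str
    names: tuple[str, ...]
    params: np.ndarray
    cov: np.ndarray | None
    sigma2: float | None
    n: int | None
    r2: float | None
    adj_r2: float | None
    knots: KnotSet | None = None
    bounds: QuartileBounds | None = None

    def __post_init__(self) -> None:
        params = np.asarray(self.params, dtype=float).ravel()
        object.__setattr__(self, "params", params)
        if len(self.names) != params.size:
            raise ValueError("one name per coefficient is required")
        if self.cov is not None:
            cov = np.asarray(self.cov, dtype=float)
            if cov.shape != (params.size, params.size):
                raise ValueError("covariance shape does not match params")
            object.__setattr__(self, "cov", cov)

    @property
    def p(self) -> int:
        """Number of non-intercept predictors actually fitted."""
        return self.params.size - 1

    @property
    def df_resid(self) -> int | None:
        return None if self.n is None else self.n - self.p - 1

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    def coefficient(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    @classmethod
    def from_coefficients(
        cls,
        family: str,
        params,
        names=None,
        knots: KnotSet | None = None,
        bounds: QuartileBounds | None = None,
    ) -> "FittedModel":
        """Wrap externally supplied coefficients (e.g. from a publication).

        The resulting model supports prediction, contrasts and interval
        coefficients but carries no covariance, so no confidence intervals.
        """
        params = np.asarray(params, dtype=float).ravel()
        if names is None:
            # derive stable names from a one-row template design
            import warnings

            probe = knots[0] if knots is not None else 0.0
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # single-point probe row
                template = design_for(family, [probe], knots=knots, bounds=bounds)
            if len(template.names) != params.size:
                raise ValueError(
                    f"{family} expects {len(template.names)} coefficients, "
                    f"got {params.size}"
                )
            names = template.names
        return cls(
            family=family, names=tuple(names), params=params,
            cov=None, sigma2=None, n=None, r2=None, adj_r2=None,
            knots=knots, bounds=bounds,
        )

    def to_report(self) -> dict[str, Any]:
        """Flat key-value summary suitable for JSON serialization."""
        out: dict[str, Any] = {
            "family": self.family,
            "n": self.n,
            "p": self.p,
            "r2": self.r2,
            "adjusted_r2": self.adj_r2,
            "coefficients": dict(zip(self.names, map(float, self.params))),
        }
        if self.cov is not None:
            se = np.sqrt(np.diag(self.cov))
            out["standard_errors"] = dict(zip(self.names, map(float, se)))
        if self.knots is not None:
            out["knots"] = list(self.knots.values)
            if self.knots.percentiles is not None:
                out["knot_percentiles"] = list(self.knots.percentiles)
        if self.bounds is not None:
            out["quartile_bounds"] = list(self.bounds.cuts)
        return out


def fit(design: BasisMatrix, y) -> FittedModel:
    """Fit OLS coefficients for a labeled design matrix.

    Raises
    ------
    InsufficientDataError
        If n <= p + 1 (no residual degrees of freedom).
    SingularDesignError
        If the design is rank-deficient; the message names the columns
        involved in the collinearity.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = design.matrix
    n, k = X.shape
    if y.size != n:
        raise ValueError(f"design has {n} rows but y has {y.size} values")
    if n <= k:
        raise InsufficientDataError(
            f"need more than {k} observations to fit {k} coefficients, got {n}"
        )

    # unit-norm column scaling for conditioning; intercept kept as-is
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0.0] = 1.0
    Xs = X / norms

    beta_s, _, rank, _ = np.linalg.lstsq(Xs, y, rcond=None)
    if rank < k:
        # identify a minimal set of columns that are linear combinations of
        # their predecessors, via QR with pivoting on the scaled design
        from scipy.linalg import qr

        R = qr(Xs, mode="r", pivoting=True)
        r_diag = np.abs(np.diag(R[0]))
        piv = R[1]
        tol = r_diag.max() * max(n, k) * np.finfo(float).eps
        bad = [design.names[piv[i]] for i in range(k) if i >= rank or r_diag[i] < tol]
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < {k}); "
            f"collinear columns: {bad}"
        )
    beta = beta_s / norms

    resid = y - X @ beta
    # one step of iterative refinement to polish ill-conditioned solves
    delta_s, *_ = np.linalg.lstsq(Xs, resid, rcond=None)
    beta = beta + delta_s / norms
    resid = y - X @ beta

    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if sst == 0.0 else 1.0 - sse / sst
    p = k - 1
    dof = n - k
    adj = 1.0 - (1.0 - r2) * (n - 1) / dof
    sigma2 = sse / dof

    # covariance via R from the scaled QR: (X'X)^-1 = S (Xs'Xs)^-1 S
    R = np.linalg.qr(Xs, mode="r")
    Rinv = np.linalg.solve(R, np.eye(k))
    cov_s = Rinv @ Rinv.T
    cov = sigma2 * cov_s / np.outer(norms, norms)

    return FittedModel(
        family=design.family,
        names=design.names,
        params=beta,
        cov=cov,
        sigma2=sigma2,
        n=n,
        r2=r2,
        adj_r2=adj,
        knots=design.knots,
        bounds=design.bounds,
    )


def adjusted_r2(model: FittedModel) -> float:
    """Explained variance penalised for model size: 1 - (1-r2)(n-1)/(n-p-1)."""
    if model.r2 is None or model.n is None:
        raise ValueError("model carries no fit statistics")
    dof = model.n - model.p - 1
    if dof <= 0:
        raise ValueError("adjusted r2 undefined: no residual degrees of freedom")
    return 1.0 - (1.0 - model.r2) * (model.n - 1) / dof


def confint(model: FittedModel, level: float = 0.95) -> dict[str, tuple[float, float]]:
    """Wald confidence intervals using t quantiles with n - p - 1 df."""
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if model.cov is None or model.df_resid is None:
        raise ValueError("model carries no covariance; intervals unavailable")
    se = np.sqrt(np.diag(model.cov))
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=model.df_resid)
    lo = model.params - tcrit * se
    hi = model.params + tcrit * se
    return {name: (float(a), float(b)) for name, a, b in zip(model.names, lo, hi)}


def bootstrap_confint(
    family: str,
    x,
    y,
    knots: KnotSet | None = None,
    bounds: QuartileBounds | None = None,
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    max_redraws: int = 100,
) -> dict[str, tuple[float, float]]:
    """Case-resampling percentile bootstrap intervals for the coefficients.

    Knots and quartile bounds are held fixed at their original-sample values
    across replicates, mirroring a pre-specified-knot workflow; only the
    rows are resampled. A replicate whose resampled design is singular
    (e.g. an empty quartile) is redrawn, up to ``max_redraws`` extra draws.
    Deterministic given ``seed``.
    """
    if B < 100:
        raise ValueError(f"at least 100 bootstrap replicates are required, got {B}")
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have the same length")

    rng = np.random.default_rng(seed)
    n = x.size
    full = fit(design_for(family, x, knots=knots, bounds=bounds), y)

    draws = np.empty((B, full.params.size))
    redraws = 0
    b = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        try:
            design = design_for(family, x[idx], knots=knots, bounds=bounds)
            draws[b] = fit(design, y[idx]).params
        except (SingularDesignError, InsufficientDataError):
            redraws += 1
            if redraws > max_redraws:
                raise SingularDesignError(
                    f"more than {max_redraws} bootstrap resamples produced "
                    "singular designs; the data are too sparse for this family"
                )
            continue
        b += 1
    if redraws:
        import warnings

        warnings.warn(
            f"{redraws} bootstrap resamples were redrawn due to singular designs",
            stacklevel=2,
        )

    alpha = 1.0 - level
    lo = np.quantile(draws, alpha / 2.0, axis=0)
    hi = np.quantile(draws, 1.0 - alpha / 2.0, axis=0)
    return {name: (float(a), float(b_)) for name, a, b_ in zip(full.names, lo, hi)}
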