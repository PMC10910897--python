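"""Percentile-based knot placement and quartile boundaries.

Knots are the exposure values at which adjacent spline intervals join.
Following Harrell's convention, knot locations default to fixed percentiles
of the observed exposure: the 10/50/90th for three knots, the 5/35/65/95th
for four. Empirical quantiles use linear interpolation between order
statistics (the "type 7" rule, numpy's default), which is what most
statistical software computes; the rule name is carried into run reports so
results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KnotSet",
    "QuartileBounds",
    "DegenerateKnotsError",
    "DEFAULT_PERCENTILES",
    "QUANTILE_RULE",
    "place_knots",
    "quartile_bounds",
]

#: Percentile defaults by knot count. The single-knot model uses the median;
#: 3 and 4 knots follow Harrell's recommendation; the 5-knot row is the
#: standard extension of that scheme and is a toolkit default.
DEFAULT_PERCENTILES: dict[int, tuple[float, ...]] = {
    1: (50.0,),
    3: (10.0, 50.0, 90.0),
    4: (5.0, 35.0, 65.0, 95.0),
    5: (5.0, 27.5, 50.0, 72.5, 95.0),
}

#: Name of the empirical-quantile estimator used throughout.
QUANTILE_RULE = "linear (type 7)"


class DegenerateKnotsError(ValueError):
    """Raised when requested knots collapse onto each other.

    Spline bases require strictly increasing knots; two percentiles mapping
    to the same data value would silently merge intervals, so we refuse.
    """


@dataclass(frozen=True)
class KnotSet:
    """An ordered set of knot locations, in exposure units.

    Parameters
    ----------
    values
        Strictly increasing knot locations.
    percentiles
        The percentages (in (0, 100)) that produced ``values``, or ``None``
        when knots were supplied directly by the user.
    source
        ``"percentile"`` or ``"user"``.
    """

    values: tuple[float, ...]
    percentiles: tuple[float, ...] | None = None
    source: str = "user"

    def __post_init__(self) -> None:
        values = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", values)
        if len(values) < 1:
            raise ValueError("a KnotSet needs at least one knot")
        if not all(np.isfinite(values)):
            raise ValueError("knot values must be finite")
        if any(b <= a for a, b in zip(values, values[1:])):
            raise DegenerateKnotsError(
                f"knot values must be strictly increasing, got {values}"
            )
        if self.source not in ("percentile", "user"):
            raise ValueError(f"unknown knot source {self.source!r}")
        if self.percentiles is not None:
            pct = tuple(float(p) for p in self.percentiles)
            object.__setattr__(self, "percentiles", pct)
            if self.source == "percentile" and len(pct) != len(values):
                raise ValueError("one percentile per knot is required")

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    def __getitem__(self, i: int) -> float:
        return self.values[i]

    @classmethod
    def from_values(cls, values) -> "KnotSet":
        """Build a user-specified KnotSet from raw exposure values."""
        return cls(values=tuple(float(v) for v in values), source="user")


@dataclass(frozen=True)
class QuartileBounds:
    """Quartile cut points of an exposure, plus its observed range."""

    q1: float
    q2: float
    q3: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not (self.min <= self.q1 <= self.q2 <= self.q3 <= self.max):
            raise ValueError(
                "quartile bounds must satisfy min <= q1 <= q2 <= q3 <= max"
            )

    @property
    def cuts(self) -> tuple[float, float, float]:
        return (self.q1, self.q2, self.q3)


def _clean_exposure(x, min_distinct: int) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if np.unique(x).size < min_distinct:
        raise DegenerateKnotsError(
            f"need at least {min_distinct} distinct finite exposure values, "
            f"got {np.unique(x).size}"
        )
    return x


def place_knots(x, n_knots: int = 3, percentiles=None) -> KnotSet:
    """Place knots at empirical percentiles of the exposure.

    Parameters
    ----------
    x
        Observed exposure values; non-finite entries are ignored.
    n_knots
        Number of knots. Without an explicit ``percentiles`` list this must
        be one of {1, 3, 4, 5}, mapped through :data:`DEFAULT_PERCENTILES`.
    percentiles
        Optional explicit percentages in (0, 100), strictly increasing;
        overrides ``n_knots``.

    Returns
    -------
    KnotSet
        Knots at the requested quantiles, strictly increasing.

    Raises
    ------
    DegenerateKnotsError
        If the data are too sparse or ties collapse two knots.
    """
    if percentiles is None:
        try:
            percentiles = DEFAULT_PERCENTILES[int(n_knots)]
        except KeyError:
            raise ValueError(
                f"no default percentiles for n_knots={n_knots}; "
                "supply an explicit percentile list"
            ) from None
    pct = tuple(float(p) for p in percentiles)
    if any(not (0.0 < p < 100.0) for p in pct):
        raise ValueError(f"percentiles must lie strictly in (0, 100): {pct}")
    if any(b <= a for a, b in zip(pct, pct[1:])):
        raise ValueError(f"percentiles must be strictly increasing: {pct}")

    x = _clean_exposure(x, min_distinct=len(pct))
    values = np.quantile(x, np.asarray(pct) / 100.0)  # linear interpolation
    if np.any(np.diff(values) <= 0):
        raise DegenerateKnotsError(
            f"ties in the data collapse knots: percentiles {pct} map to "
            f"{tuple(values)}"
        )
    return KnotSet(values=tuple(values), percentiles=pct, source="percentile")


def quartile_bounds(x) -> QuartileBounds:
    """Quartile cut points under the same quantile rule as :func:`place_knots`."""
    x = _clean_exposure(x, min_distinct=4)
    q1, q2, q3 = np.quantile(x, [0.25, 0.50, 0.75])
    return QuartileBounds(
        q1=float(q1), q2=float(q2), q3=float(q3),
        min=float(x.min()), max=float(x.max()),
    )
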