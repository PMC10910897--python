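"""Independent oracles used by the test suite.

``exact_ols`` solves the least-squares normal equations in exact rational
arithmetic. Floating-point inputs are dyadic rationals, so Fractions built
from them are exact and every Gram-matrix entry and elimination step is
computed without rounding; the only rounding is the final conversion of
each coefficient back to float. This is independent of both the package's
QR-based solver and any library least-squares routine.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np


def _solve_exact(A: list[list[Fraction]], b: list[Fraction]) -> list[Fraction]:
    """Gaussian elimination with partial pivoting over the rationals."""
    k = len(b)
    M = [row[:] + [rhs] for row, rhs in zip(A, b)]
    for col in range(k):
        pivot = max(range(col, k), key=lambda r: abs(M[r][col]))
        if M[pivot][col] == 0:
            raise ZeroDivisionError("singular system")
        M[col], M[pivot] = M[pivot], M[col]
        for r in range(k):
            if r != col and M[r][col] != 0:
                factor = M[r][col] / M[col][col]
                M[r] = [a - factor * p for a, p in zip(M[r], M[col])]
    return [M[i][k] / M[i][i] for i in range(k)]


def exact_ols(X, y) -> np.ndarray:
    """Exact-rational OLS coefficients for design X and response y."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    Xf = [[Fraction(v) for v in row] for row in X]
    yf = [Fraction(v) for v in y]
    gram = [
        [sum(Xf[i][a] * Xf[i][b] for i in range(n)) for b in range(k)]
        for a in range(k)
    ]
    rhs = [sum(Xf[i][a] * yf[i] for i in range(n)) for a in range(k)]
    beta = _solve_exact(gram, rhs)
    return np.array([float(b) for b in beta])


def brute_force_quantile(x, p: float) -> float:
    """Quantile by sorting and linearly interpolating order statistics.

    With sorted values x_(1) <= ... <= x_(n), the p-th quantile sits at
    fractional rank h = (n - 1) * p / 100 and interpolates linearly between
    the bracketing order statistics.
    """
    xs = sorted(float(v) for v in np.asarray(x).ravel())
    n = len(xs)
    h = (n - 1) * p / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    frac = h - lo
    return xs[lo] * (1.0 - frac) + xs[hi] * frac
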