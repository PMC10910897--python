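"""Multi-model comparison reports.

Runs the standard five-family comparison (simple linear, quadratic,
quartile categorization, 1- and 3-knot linear splines, 3-knot restricted
cubic spline) on one exposure–outcome dataset and collects coefficient
tables, interval-coefficient tables, an adjusted-r2 table and prediction
curves. Every number in a report is a pure function of the input data and
the recorded metadata (quantile rule, knots, seed), so reruns are
byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .basis import design_for
from .fitting import FittedModel, fit
from .interpretation import lsp_interval_slopes, predict, rcs_interval_coeffs
from .knots import QUANTILE_RULE, place_knots, quartile_bounds

__all__ = ["ComparisonReport", "DEFAULT_MODELS", "run_comparison", "export_curves", "load_dataset"]

logger = logging.getLogger("splinereg")

#: Model keys of the default comparison, in report order.
DEFAULT_MODELS = (
    "linear",
    "quadratic",
    "categorical",
    "lsp_1knot",
    "lsp_3knot",
    "rcs_3knot",
)

_MODEL_SPECS: dict[str, tuple[str, int | None]] = {
    # key -> (family, n_knots or None)
    "linear": ("linear", None),
    "quadratic": ("quadratic", None),
    "categorical": ("categorical", None),
    "lsp_1knot": ("lsp", 1),
    "lsp_3knot": ("lsp", 3),
    "rcs_3knot": ("rcs", 3),
}


@dataclass(frozen=True)
class ComparisonReport:
    """All outputs of one comparison run."""

    models: dict[str, FittedModel]
    coefficients: pd.DataFrame
    interval_coefficients: pd.DataFrame
    adjusted_r2: pd.DataFrame
    metadata: dict[str, Any]

    def to_json_dict(self) -> dict[str, Any]:
        return {
            "metadata": self.metadata,
            "models": {key: m.to_report() for key, m in self.models.items()},
        }

    def write(self, outdir) -> list[Path]:
        """Write the report tables to CSV (+ JSON metadata); returns paths."""
        import json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, frame in (
            ("coefficients", self.coefficients),
            ("interval_coefficients", self.interval_coefficients),
            ("adjusted_r2", self.adjusted_r2),
        ):
            path = outdir / f"{name}.csv"
            frame.to_csv(path, index=False)
            written.append(path)
        path = outdir / "report.json"
        path.write_text(json.dumps(self.to_json_dict(), indent=2, sort_keys=True))
        written.append(path)
        return written


def load_dataset(path) -> pd.DataFrame:
    """Read a two-column exposure/outcome CSV, dropping incomplete rows.

    The first column is taken as the exposure and the second as the outcome,
    whatever their headers; the number of dropped rows is logged.
    """
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two numeric columns, found {frame.shape[1]}")
    frame = frame.iloc[:, :2].copy()
    frame.columns = ["exposure", "outcome"]
    for col in frame.columns:
        frame[col] = pd.to_numeric(frame[col], errors="raise")
    n_total = len(frame)
    frame = frame.dropna()
    n_dropped = n_total - len(frame)
    if n_dropped:
        logger.info("dropped %d incomplete rows (of %d)", n_dropped, n_total)
    return frame.reset_index(drop=True)


def _fit_one(key: str, x: np.ndarray, y: np.ndarray) -> FittedModel:
    family, n_knots = _MODEL_SPECS[key]
    knots = bounds = None
    if family in ("lsp", "rcs"):
        knots = place_knots(x, n_knots=n_knots)
    elif family == "categorical":
        bounds = quartile_bounds(x)
    return fit(design_for(family, x, knots=knots, bounds=bounds), y)


def _coefficient_rows(key: str, model: FittedModel) -> list[dict[str, Any]]:
    rows = []
    se = np.sqrt(np.diag(model.cov)) if model.cov is not None else [np.nan] * len(model.names)
    for name, value, s in zip(model.names, model.params, se):
        rows.append(
            {"model": key, "term": name, "estimate": float(value), "se": float(s)}
        )
    return rows


def _interval_rows(key: str, model: FittedModel) -> list[dict[str, Any]]:
    rows: list[dict[str, Any]] = []
    if model.family == "lsp":
        ic = lsp_interval_slopes(model)
        for (lo, hi), value, how in zip(ic.intervals, ic.values, ic.derivation):
            rows.append(
                {
                    "model": key,
                    "interval_low": lo,
                    "interval_high": hi,
                    "kind": "slope",
                    "value": value,
                    "derivation": how,
                }
            )
    elif model.family == "rcs":
        coeffs = rcs_interval_coeffs(model.coefficient("rcs1"), model.knots)
        for k, value, label in zip(model.knots, coeffs, ("beta2*", "beta3*", "beta4*")):
            rows.append(
                {
                    "model": key,
                    "interval_low": k,
                    "interval_high": np.inf,
                    "kind": "cubic",
                    "value": value,
                    "derivation": label,
                }
            )
    return rows


def run_comparison(
    data,
    models: Sequence[str] = DEFAULT_MODELS,
    seed: int | None = None,
) -> ComparisonReport:
    """Fit the requested model families to one dataset and tabulate results.

    Parameters
    ----------
    data
        Path to a two-column CSV, or a DataFrame whose first two columns are
        exposure and outcome.
    models
        Subset of :data:`DEFAULT_MODELS` keys, fitted in the given order.
    seed
        Recorded in the metadata (relevant when callers add bootstrap
        intervals); the comparison itself is deterministic.
    """
    if isinstance(data, (str, Path)):
        frame = load_dataset(data)
        source = str(data)
    else:
        frame = data.iloc[:, :2].copy()
        frame.columns = ["exposure", "outcome"]
        n_before = len(frame)
        frame = frame.dropna().reset_index(drop=True)
        if len(frame) < n_before:
            logger.info("dropped %d incomplete rows", n_before - len(frame))
        source = "<in-memory>"

    unknown = [m for m in models if m not in _MODEL_SPECS]
    if unknown:
        raise ValueError(f"unknown model keys: {unknown}; choose from {list(_MODEL_SPECS)}")

    x = frame["exposure"].to_numpy(dtype=float)
    y = frame["outcome"].to_numpy(dtype=float)

    fitted: dict[str, FittedModel] = {}
    coef_rows: list[dict[str, Any]] = []
    interval_rows: list[dict[str, Any]] = []
    r2_rows: list[dict[str, Any]] = []
    for key in models:
        model = _fit_one(key, x, y)
        fitted[key] = model
        coef_rows.extend(_coefficient_rows(key, model))
        interval_rows.extend(_interval_rows(key, model))
        r2_rows.append(
            {"model": key, "r2": model.r2, "adjusted_r2": model.adj_r2, "p": model.p}
        )
        if model.knots is not None:
            logger.info("%s: knots %s", key, list(model.knots.values))

    logger.info(
        "fitted %d models on n=%d observations (quantile rule: %s)",
        len(fitted), len(frame), QUANTILE_RULE,
    )

    metadata = {
        "source": source,
        "n": int(len(frame)),
        "models": list(models),
        "quantile_rule": QUANTILE_RULE,
        "seed": seed,
        "toolkit_version": __version__,
    }
    return ComparisonReport(
        models=fitted,
        coefficients=pd.DataFrame(coef_rows),
        interval_coefficients=pd.DataFrame(interval_rows),
        adjusted_r2=pd.DataFrame(r2_rows),
        metadata=metadata,
    )


def export_curves(
    models: dict[str, FittedModel],
    grid,
    level: float = 0.95,
    outdir=None,
) -> dict[str, pd.DataFrame]:
    """Prediction curves (fit and pointwise CI) for each model on one grid.

    Returns one DataFrame per model with columns x, fit, ci_low, ci_high,
    extrapolated; if ``outdir`` is given each is also written to
    ``curve_<model>.csv``.
    """
    grid = np.asarray(grid, dtype=float).ravel()
    if grid.size == 0:
        raise ValueError("empty prediction grid")
    curves: dict[str, pd.DataFrame] = {}
    for key, model in models.items():
        pc = predict(model, grid, level=level)
        curves[key] = pd.DataFrame(
            {
                "x": pc.x,
                "fit": pc.fit,
                "ci_low": pc.ci_low,
                "ci_high": pc.ci_high,
                "extrapolated": pc.extrapolated,
            }
        )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for key, frame in curves.items():
            frame.to_csv(outdir / f"curve_{key}.csv", index=False)
    return curves


def default_grid(x, n_points: int = 200) -> np.ndarray:
    """Evenly spaced prediction grid over the observed exposure range."""
    x = np.asarray(x, dtype=float)
    return np.linspace(np.nanmin(x), np.nanmax(x), n_points)
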