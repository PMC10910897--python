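"""Shared fixtures: the published worked-example models and small datasets."""

from __future__ import annotations

import numpy as np
import pytest

from splinereg import (
    FittedModel,
    KnotSet,
    QuartileBounds,
    example_study_config,
    generate,
)

#: Knot locations of the skinfold example (mm): 10th/50th/90th percentiles.
EXAMPLE_KNOTS = KnotSet(
    values=(212.0, 330.0, 621.4),
    percentiles=(10.0, 50.0, 90.0),
    source="percentile",
)

#: Published coefficient sets of the worked example, by model key.
PUBLISHED_COEFFS = {
    "linear": (64.0658, -0.0304),
    "quadratic": (73.2212, -0.0746, 0.00004),
    "categorical": (60.1339, -4.9870, -10.0695, -15.1727),
    "lsp_1knot": (77.5648, -0.0810, 0.0632),
    "lsp_3knot": (64.1788, -0.0156, -0.0671, 0.0601, 0.0128),
    "rcs_3knot": (75.9306, -0.0738, 0.0740),
}

#: Synthetic stand-in quartile bounds for the categorization example. Only
#: the top cut is anchored by the publication (the upper quartile starts at
#: 458 mm); the others are plausible values for a right-skewed exposure.
EXAMPLE_BOUNDS = QuartileBounds(q1=255.0, q2=330.0, q3=457.9, min=150.0, max=1153.0)


@pytest.fixture(scope="session")
def example_knots() -> KnotSet:
    return EXAMPLE_KNOTS


@pytest.fixture(scope="session")
def one_knot() -> KnotSet:
    return KnotSet(values=(330.0,), percentiles=(50.0,), source="percentile")


@pytest.fixture(scope="session")
def published_models(one_knot, example_knots) -> dict[str, FittedModel]:
    """Published coefficients wrapped as FittedModels (no covariance)."""
    return {
        "linear": FittedModel.from_coefficients("linear", PUBLISHED_COEFFS["linear"]),
        "quadratic": FittedModel.from_coefficients("quadratic", PUBLISHED_COEFFS["quadratic"]),
        "categorical": FittedModel.from_coefficients(
            "categorical", PUBLISHED_COEFFS["categorical"], bounds=EXAMPLE_BOUNDS
        ),
        "lsp_1knot": FittedModel.from_coefficients(
            "lsp", PUBLISHED_COEFFS["lsp_1knot"], knots=one_knot
        ),
        "lsp_3knot": FittedModel.from_coefficients(
            "lsp", PUBLISHED_COEFFS["lsp_3knot"], knots=example_knots
        ),
        "rcs_3knot": FittedModel.from_coefficients(
            "rcs", PUBLISHED_COEFFS["rcs_3knot"], knots=example_knots
        ),
    }


@pytest.fixture(scope="session")
def study_dataset():
    """One draw from the study-like generator (n = 315)."""
    return generate(example_study_config(n=315, seed=20260927))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
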