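"""Shared fixtures: a small study grid, environmental stack and virtual
species, plus independent oracle implementations used across test modules."""

from __future__ import annotations

import math

import numpy as np
import pytest

from shaderange.grids import CLIMATIC, EDAPHIC, GridSpec
from shaderange.synthetic import (
    LayerSpec,
    NicheResponse,
    SpeciesNicheTruth,
    generate_env_stack,
    generate_land_mask,
)

SIX_LAYERS = [
    LayerSpec("BIO1", CLIMATIC, mean=26.0, sd=1.5, smoothing=5.0, gradient=-0.4),
    LayerSpec("BIO4", CLIMATIC, mean=150.0, sd=40.0, smoothing=6.0, gradient=8.0),
    LayerSpec("BIO12", CLIMATIC, mean=1800.0, sd=400.0, smoothing=5.0, gradient=-80.0),
    LayerSpec("BIO18", CLIMATIC, mean=450.0, sd=120.0, smoothing=4.0),
    LayerSpec("phh2o", EDAPHIC, mean=58.0, sd=6.0, smoothing=3.0),
    LayerSpec("cec", EDAPHIC, mean=160.0, sd=35.0, smoothing=3.0),
]


@pytest.fixture(scope="session")
def grid_small() -> GridSpec:
    # 48 x 48 cells at 2.5 arc-min over a 2 x 2 degree box
    return GridSpec.from_bounds(-10.0, 2.0, -8.0, 4.0)


@pytest.fixture(scope="session")
def env_small(grid_small):
    mask = generate_land_mask(grid_small, ocean_fraction=0.2, seed=11)
    return generate_env_stack(grid_small, SIX_LAYERS, seed=42, nodata_mask=mask)


@pytest.fixture(scope="session")
def truth_two_layer() -> SpeciesNicheTruth:
    """Virtual species whose niche uses exactly 2 of the 6 layers."""
    return SpeciesNicheTruth("vs1", {
        "BIO1": NicheResponse(26.0, 1.2),
        "BIO12": NicheResponse(1900.0, 300.0),
    }, prevalence_target=0.3)


# ---------------------------------------------------------------------------
# independent oracles (deliberately different code paths from the package)
# ---------------------------------------------------------------------------

def oracle_haversine_km(lon1, lat1, lon2, lat2) -> float:
    """Scalar great-circle distance via the spherical law of cosines."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    c = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return 6371.0 * math.acos(min(1.0, max(-1.0, c)))


def oracle_auc(scores, labels) -> float:
    """O(n^2) concordant-pair counting with ties at 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def oracle_best_threshold_grid(scores, labels, step: float = 1e-3) -> float:
    """Best sensitivity+specificity over a fixed threshold grid."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    best = -np.inf
    for t in np.arange(step, 1.0, step):
        pred = scores >= t
        sens = pred[labels == 1].mean()
        spec = (~pred[labels == 0]).mean()
        best = max(best, sens + spec - 1.0)
    return float(best)


def oracle_equicorrelated_vif(k: int, r: float) -> float:
    """Closed-form VIF for one of k equicorrelated predictors.

    Multiple correlation of one variable on the other k-1 under an
    equicorrelation matrix: R^2 = (k-1) r^2 / (1 + (k-2) r).
    """
    r2 = (k - 1) * r**2 / (1.0 + (k - 2) * r)
    return 1.0 / (1.0 - r2)


def exact_correlated_matrix(n: int, corr: np.ndarray, seed: int = 0) -> np.ndarray:
    """Sample matrix whose *empirical* correlation equals ``corr`` exactly.

    Whitens a random draw against its own sample covariance, then colors it
    with the Cholesky factor of the target correlation.
    """
    rng = np.random.default_rng(seed)
    k = corr.shape[0]
    X = rng.standard_normal((n, k))
    X = X - X.mean(axis=0)
    cov = X.T @ X / n
    X = X @ np.linalg.inv(np.linalg.cholesky(cov)).T
    return X @ np.linalg.cholesky(corr).T
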