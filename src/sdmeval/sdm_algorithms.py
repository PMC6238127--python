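"""Suitability models: climate envelope (BIOCLIM-style), Gower similarity
(DOMAIN-style) and a binomial GLM with logit link, plus an importer for
externally produced suitability rasters.

All three models are implemented from first principles.  The envelope
model scores a cell by the two-tailed empirical percentile
``2 * min(F, 1 - F)`` of its value among the training presences (midrank
convention), takes the minimum across layers, and hard-zeroes anything
outside the per-layer training min/max.  The similarity model scores a
cell by ``max over training points of (1 - Gower distance)`` where the
Gower distance is the range-normalized mean absolute difference.  The GLM
is fitted by iteratively reweighted least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from sdmeval.rasters_io import EnvStack, GridRaster

logger = logging.getLogger(__name__)

_MIN_PRESENCES = 5


def _training_matrix(train: pd.DataFrame, layer_names: list[str]) -> np.ndarray:
    if "valid" in train.columns:
        train = train[train["valid"]]
    X = train[layer_names].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("training table contains missing values")
    return X


# ---------------------------------------------------------------------------
# climate envelope
# ---------------------------------------------------------------------------

@dataclass
class BioclimModel:
    layer_names: list[str]
    sorted_samples: dict[str, np.ndarray]   # per-layer sorted training values
    envelopes: dict[str, tuple[float, float]]


def fit_bioclim(train: pd.DataFrame, layer_names: list[str]) -> BioclimModel:
    """Fit the envelope model from presence predictor vectors."""
    X = _training_matrix(train, layer_names)
    if X.shape[0] < _MIN_PRESENCES:
        raise ValueError(f"need at least {_MIN_PRESENCES} presences, got {X.shape[0]}")
    sorted_samples = {}
    envelopes = {}
    for j, name in enumerate(layer_names):
        s = np.sort(X[:, j])
        sorted_samples[name] = s
        envelopes[name] = (float(s[0]), float(s[-1]))
    return BioclimModel(list(layer_names), sorted_samples, envelopes)


def _tail_score(sorted_vals: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Two-tailed percentile score 2*min(F, 1-F), F by midrank, 0 outside
    the [min, max] envelope."""
    n = len(sorted_vals)
    lo = np.searchsorted(sorted_vals, x, side="left")
    hi = np.searchsorted(sorted_vals, x, side="right")
    f = (lo + 0.5 * (hi - lo)) / n
    t = 2.0 * np.minimum(f, 1.0 - f)
    t = np.clip(t, 0.0, 1.0)
    outside = (x < sorted_vals[0]) | (x > sorted_vals[-1])
    return np.where(outside, 0.0, t)


def predict_bioclim(m: BioclimModel, stack: EnvStack) -> GridRaster:
    """Score every valid cell of the stack with the envelope model."""
    _check_layers(m.layer_names, stack)
    template = stack.template
    score = np.full(template.shape, np.inf)
    for name in m.layer_names:
        vals = stack[name].values
        t = _tail_score(m.sorted_samples[name], vals)
        score = np.minimum(score, t)
    score = np.where(template.valid_mask, score, np.nan)
    return template.copy_with(score)


# ---------------------------------------------------------------------------
# Gower similarity
# ---------------------------------------------------------------------------

@dataclass
class DomainModel:
    layer_names: list[str]
    train: np.ndarray                       # (n_points, n_layers)
    ranges: np.ndarray                      # per-layer max - min over training

    def __post_init__(self) -> None:
        zero = np.nonzero(self.ranges <= 0)[0]
        if len(zero):
            bad = [self.layer_names[i] for i in zero]
            raise ValueError(f"zero training range on layer(s): {bad}")


def fit_domain(train: pd.DataFrame, layer_names: list[str]) -> DomainModel:
    X = _training_matrix(train, layer_names)
    if X.shape[0] < _MIN_PRESENCES:
        raise ValueError(f"need at least {_MIN_PRESENCES} presences, got {X.shape[0]}")
    ranges = X.max(axis=0) - X.min(axis=0)
    return DomainModel(list(layer_names), X, ranges)


def predict_domain(m: DomainModel, stack: EnvStack, chunk: int = 2048) -> GridRaster:
    """Similarity of each cell to its most similar training record.

    Gower distance d(a, b) = mean_k |a_k - b_k| / range_k; similarity is
    ``max_points (1 - d)`` clamped to [0, 1].
    """
    _check_layers(m.layer_names, stack)
    template = stack.template
    env = stack.as_array(m.layer_names).reshape(len(m.layer_names), -1).T  # (cells, L)
    valid = template.valid_mask.ravel()
    out = np.full(env.shape[0], np.nan)
    idx = np.nonzero(valid)[0]
    scaled_train = m.train / m.ranges                                      # (P, L)
    for start in range(0, len(idx), chunk):
        sel = idx[start:start + chunk]
        a = env[sel] / m.ranges                                            # (chunk, L)
        d = np.abs(a[:, None, :] - scaled_train[None, :, :]).mean(axis=2)  # (chunk, P)
        out[sel] = np.clip(1.0 - d.min(axis=1), 0.0, 1.0)
    return template.copy_with(out.reshape(template.shape))


# ---------------------------------------------------------------------------
# binomial GLM (logit link)
# ---------------------------------------------------------------------------

@dataclass
class GlmModel:
    layer_names: list[str]
    coef: np.ndarray                        # intercept first
    std_errors: np.ndarray
    deviance: float
    n_iter: int
    converged: bool
    separation: bool = False

    @property
    def intercept(self) -> float:
        return float(self.coef[0])


_GLM_TOL = 1e-8
_GLM_MAX_ITER = 100
_SEPARATION_COEF = 30.0  # |linear predictor coefficient| beyond which we call separation


def fit_glm(train: pd.DataFrame, layer_names: list[str]) -> GlmModel:
    """Fit a binomial GLM (logit link, linear terms only) by IRLS.

    Expects a table with presence and absence rows (``label`` column).
    Convergence: relative deviance change < 1e-8 or 100 iterations.
    Complete separation is detected via diverging coefficients; the fit
    is then returned at the iteration cap with ``separation=True``.
    """
    if "valid" in train.columns:
        train = train[train["valid"]]
    y = (train["label"] == "presence").to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("fit_glm needs both presence and absence records")
    X = train[list(layer_names)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("training table contains missing values")
    X = np.column_stack([np.ones(len(y)), X])

    beta = np.zeros(X.shape[1])
    deviance = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, _GLM_MAX_ITER + 1):
        eta = X @ beta
        mu = expit(eta)
        mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        wx = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ wx, wx.T @ z)
        new_dev = -2.0 * np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu))
        if np.isfinite(deviance) and abs(deviance - new_dev) < _GLM_TOL * (abs(deviance) + 0.1):
            beta = beta_new
            deviance = new_dev
            converged = True
            break
        beta = beta_new
        deviance = new_dev

    separation = bool(np.abs(beta).max() > _SEPARATION_COEF)
    if separation:
        logger.warning("fit_glm: complete separation suspected "
                       "(max |coef| = %.3g at iteration cap)", np.abs(beta).max())

    eta = X @ beta
    mu = np.clip(expit(eta), 1e-12, 1.0 - 1e-12)
    w = mu * (1.0 - mu)
    try:
        cov = np.linalg.inv(X.T @ (X * w[:, None]))
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)

    return GlmModel(list(layer_names), beta, se, float(deviance), n_iter,
                    converged, separation)


def predict_glm(m: GlmModel, stack: EnvStack) -> GridRaster:
    """Per-cell logistic(intercept + sum slope_k * env_k)."""
    _check_layers(m.layer_names, stack)
    template = stack.template
    env = stack.as_array(m.layer_names)
    lin = m.coef[0] + np.tensordot(m.coef[1:], env, axes=1)
    suit = expit(lin)
    suit = np.where(template.valid_mask, suit, np.nan)
    return template.copy_with(suit)


# ---------------------------------------------------------------------------
# external predictions
# ---------------------------------------------------------------------------

def import_prediction(r: GridRaster, template: GridRaster,
                      rescale: bool = False) -> GridRaster:
    """Ingest an externally produced suitability raster.

    Checks alignment with the analysis grid; with ``rescale=True``
    min-max rescales values to [0, 1] (error on constant rasters).
    """
    if not template.georef_matches(r):
        raise ValueError(
            "imported raster does not align with the analysis grid: "
            f"shape {r.shape} vs {template.shape}, "
            f"origin ({r.x_origin}, {r.y_origin}) vs "
            f"({template.x_origin}, {template.y_origin}), "
            f"cell_size {r.cell_size} vs {template.cell_size}")
    values = r.values.copy()
    if rescale:
        lo = np.nanmin(values)
        hi = np.nanmax(values)
        if hi == lo:
            raise ValueError("cannot rescale a constant raster (zero range)")
        values = (values - lo) / (hi - lo)
    return r.copy_with(values)


def _check_layers(model_layers: list[str], stack: EnvStack) -> None:
    missing = set(model_layers) - set(stack.names)
    if missing:
        raise ValueError(f"stack is missing model layers: {sorted(missing)}")
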