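"""Data-preparation rules: empirical-distribution construction from
peripheral presences, minimum-distance thinning, random subsetting, and
collinearity-based predictor selection."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from sdmeval.rasters_io import CategoricalMap, GridRaster, OccurrenceSet

logger = logging.getLogger(__name__)


@dataclass
class EDConfig:
    """Buffers (map units) used to dilate presences into a range map.

    ``buffer_abrupt`` applies where ``abrupt_mask`` is 1 (zones of abrupt
    environmental change, e.g. mountains); ``buffer_default`` elsewhere.
    """

    buffer_default: float = 30.0
    buffer_abrupt: float = 5.0
    abrupt_mask: CategoricalMap | None = None

    def __post_init__(self) -> None:
        if self.buffer_default < 0 or self.buffer_abrupt < 0:
            raise ValueError("buffers must be >= 0")
        if self.buffer_abrupt > self.buffer_default:
            raise ValueError("buffer_abrupt must not exceed buffer_default")


def build_ed(presences: OccurrenceSet, grid: GridRaster | CategoricalMap,
             cfg: EDConfig) -> CategoricalMap:
    """Delimit an empirical-distribution map by buffering presence points.

    A cell is 1 iff its center lies within the applicable buffer
    (``buffer_abrupt`` where the abrupt mask is set, ``buffer_default``
    elsewhere) of any presence point; distances are planar Euclidean.
    """
    pres = presences.presences
    if len(pres) == 0:
        raise ValueError("build_ed requires at least one presence")
    rr, cc = np.indices(grid.shape)
    cx, cy = grid.cell_center(rr.ravel(), cc.ravel())
    centers = np.column_stack([cx, cy])
    # distance from each cell center to the nearest presence point
    dmin = cdist(centers, pres.xy).min(axis=1).reshape(grid.shape)

    buffers = np.full(grid.shape, cfg.buffer_default, dtype=float)
    if cfg.abrupt_mask is not None:
        if not grid.georef_matches(cfg.abrupt_mask):
            raise ValueError("abrupt_mask georeference differs from the template grid")
        buffers[cfg.abrupt_mask.values == 1] = cfg.buffer_abrupt

    values = np.where(dmin <= buffers, 1, 0)
    valid = grid.valid_mask
    values = np.where(valid, values, -1)
    return CategoricalMap(values=values, x_origin=grid.x_origin,
                          y_origin=grid.y_origin, cell_size=grid.cell_size)


def thin_points(pts: OccurrenceSet, min_dist: float, seed: int) -> OccurrenceSet:
    """Greedy minimum-distance thinning over a seeded random permutation.

    Visits points in a random order and accepts each one iff it lies at
    least ``min_dist`` from every already-accepted point, so all pairwise
    output distances are >= ``min_dist``.  Deterministic per seed; the
    accepted set is maximal with respect to its own permutation.
    """
    if min_dist < 0:
        raise ValueError("min_dist must be >= 0")
    n = len(pts)
    if n == 0 or min_dist == 0:
        return pts
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    xy = pts.xy
    accepted: list[int] = []
    for i in order:
        if not accepted:
            accepted.append(i)
            continue
        d = np.hypot(*(xy[accepted] - xy[i]).T)
        if (d >= min_dist).all():
            accepted.append(i)
    accepted.sort()
    mask = np.zeros(n, dtype=bool)
    mask[accepted] = True
    return pts.subset(mask)


def subsample(pts: OccurrenceSet, n: int, seed: int) -> OccurrenceSet:
    """Uniform random subset of size ``n``, deterministic per seed."""
    if n > len(pts):
        raise ValueError(f"cannot subsample {n} from {len(pts)} points")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pts), size=n, replace=False)
    mask = np.zeros(len(pts), dtype=bool)
    mask[idx] = True
    return pts.subset(mask)


def select_predictors(table: pd.DataFrame, layer_names: list[str],
                      threshold: float = 0.7,
                      priority: list[str] | None = None):
    """Greedy low-collinearity predictor selection by Spearman correlation.

    Scans layers in ``priority`` order (default: ``layer_names`` order)
    and keeps a layer iff its absolute Spearman rho with every
    already-kept layer is below ``threshold``.  Rho uses average ranks
    for ties.  Constant layers (undefined rho) are excluded with a
    warning.

    Returns ``(kept_names, rho_matrix)`` where ``rho_matrix`` is the full
    pairwise Spearman matrix as a DataFrame.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 points to estimate correlations")
    priority = list(priority) if priority is not None else list(layer_names)
    unknown = set(priority) - set(layer_names)
    if unknown:
        raise ValueError(f"priority names not in layer_names: {sorted(unknown)}")

    data = table[layer_names].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns raise a scipy warning
        rho, _ = stats.spearmanr(data)
    rho = np.atleast_2d(rho)
    if rho.shape != (len(layer_names), len(layer_names)):
        # spearmanr collapses the 2-layer case to a scalar
        r = float(rho.ravel()[0])
        rho = np.array([[1.0, r], [r, 1.0]])
    rho_df = pd.DataFrame(rho, index=layer_names, columns=layer_names)

    constant = [n for n in layer_names if np.nanstd(data[:, layer_names.index(n)]) == 0]
    for name in constant:
        logger.warning("select_predictors: layer %r is constant (undefined rho); excluded",
                       name)

    kept: list[str] = []
    for name in priority:
        if name in constant:
            continue
        rhos = rho_df.loc[name, kept].to_numpy(dtype=float) if kept else np.array([])
        if np.all(np.abs(rhos) < threshold):
            kept.append(name)
    return kept, rho_df
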