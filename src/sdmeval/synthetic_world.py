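"""Virtual-species world generator.

Builds spatially autocorrelated predictor layers, a logistic true
suitability surface with a known range map (optionally including disjunct
satellite patches), and seeded presence / true-absence samplers — giving
every downstream modelling and comparison stage a full ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import expit

from sdmeval.rasters_io import CategoricalMap, EnvStack, GridRaster, OccurrenceSet


@dataclass
class WorldConfig:
    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 1.0
    n_predictors: int = 4
    autocorr_length: float = 5.0
    seed: int = 0
    # each entry (source layer name, mixing weight, noise sd) appends one
    # derived layer correlated with its source
    collinearity_spec: list[tuple[str, float, float]] = field(default_factory=list)
    x_origin: float = 0.0
    y_origin: float | None = None  # default: n_rows * cell_size (yll = 0)

    def __post_init__(self) -> None:
        if self.n_predictors < 2:
            raise ValueError("n_predictors must be >= 2")
        if self.autocorr_length < 0:
            raise ValueError("autocorr_length must be >= 0")
        if min(self.n_rows, self.n_cols) < 8:
            raise ValueError("degenerate world: need at least 8 cells a side")
        if self.y_origin is None:
            self.y_origin = self.n_rows * self.cell_size


@dataclass
class VirtualSpecies:
    """Ground-truth species: suitability coefficients, surface and range."""

    beta: np.ndarray                # intercept followed by one slope per layer
    suitability_cutoff: float
    layer_names: list[str]
    true_suitability: GridRaster
    true_range: CategoricalMap
    satellite_spec: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def prevalence(self) -> float:
        """Fraction of valid cells inside the true range."""
        valid = self.true_range.valid_mask
        return float((self.true_range.values[valid] == 1).mean())


def _smooth(field_: np.ndarray, scale: float) -> np.ndarray:
    if scale <= 0:
        return field_
    # truncated Gaussian kernel, radius 3 * autocorr_length
    return ndimage.gaussian_filter(field_, sigma=scale, truncate=3.0, mode="nearest")


def _standardize(field_: np.ndarray) -> np.ndarray:
    mu = field_.mean()
    sd = field_.std()
    if sd == 0:
        raise ValueError("degenerate predictor: zero variance after smoothing")
    return (field_ - mu) / sd


def generate_predictors(cfg: WorldConfig) -> EnvStack:
    """Generate the predictor stack for a world.

    Each base layer is white noise smoothed at ``autocorr_length`` and
    standardized to mean 0, sd 1; ``collinearity_spec`` layers are built
    as ``weight * source + noise`` so pairwise correlation is
    controllable.  Deterministic per seed.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.n_rows, cfg.n_cols)
    layers: dict[str, GridRaster] = {}

    def as_raster(arr: np.ndarray) -> GridRaster:
        return GridRaster(values=arr, x_origin=cfg.x_origin, y_origin=cfg.y_origin,
                          cell_size=cfg.cell_size)

    for k in range(cfg.n_predictors):
        raw = _smooth(rng.standard_normal(shape), cfg.autocorr_length)
        layers[f"env{k + 1:02d}"] = as_raster(_standardize(raw))

    for j, (source, weight, noise_sd) in enumerate(cfg.collinearity_spec):
        if source not in layers:
            raise ValueError(f"collinearity_spec source {source!r} not generated yet")
        mixed = weight * layers[source].values + noise_sd * rng.standard_normal(shape)
        layers[f"colin{j + 1:02d}"] = as_raster(_standardize(mixed))

    return EnvStack(layers)


def _satellite_mask(shape: tuple[int, int], patches) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = np.indices(shape)
    for (pr, pc, radius) in patches:
        mask |= (rr - pr) ** 2 + (cc - pc) ** 2 <= radius ** 2
    return mask


def define_species(stack: EnvStack, beta, cutoff: float,
                   satellite_spec=None) -> VirtualSpecies:
    """Define the true species on a predictor stack.

    Suitability is ``logistic(beta0 + sum_k beta_k * env_k)``; the true
    range is the cells at or above ``cutoff``, plus any satellite patches
    (``(row, col, radius_cells)`` discs force-added regardless of climate,
    emulating disjunct isolated populations).
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (len(stack) + 1,):
        raise ValueError(f"beta must have length n_layers + 1 = {len(stack) + 1}")
    if not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must lie in (0, 1)")
    satellite_spec = list(satellite_spec or [])

    env = stack.as_array()                      # (L, R, C)
    lin = beta[0] + np.tensordot(beta[1:], env, axes=1)
    suit = expit(lin)
    valid = stack.template.valid_mask
    suit = np.where(valid, suit, np.nan)

    range_vals = np.where(suit >= cutoff, 1, 0)
    if satellite_spec:
        range_vals = np.where(_satellite_mask(suit.shape, satellite_spec), 1, range_vals)
    range_vals = np.where(valid, range_vals, -1)
    if not (range_vals == 1).any():
        raise ValueError(
            f"empty true range: no cell reaches cutoff {cutoff} "
            f"(max suitability {np.nanmax(suit):.4f})")

    t = stack.template
    return VirtualSpecies(
        beta=beta,
        suitability_cutoff=cutoff,
        layer_names=stack.names,
        true_suitability=t.copy_with(suit),
        true_range=CategoricalMap(values=range_vals, x_origin=t.x_origin,
                                  y_origin=t.y_origin, cell_size=t.cell_size),
        satellite_spec=satellite_spec,
    )


def _cells_to_points(grid, rows, cols, label: str) -> OccurrenceSet:
    x, y = grid.cell_center(rows, cols)
    return OccurrenceSet.from_arrays(x, y, label)


def sample_presences(vs: VirtualSpecies, n: int, seed: int) -> OccurrenceSet:
    """Draw ``n`` presence points at distinct true-range cell centers,
    with probability proportional to true suitability (one per cell)."""
    rng = np.random.default_rng(seed)
    tr = vs.true_range
    rows, cols = np.nonzero(tr.values == 1)
    if len(rows) == 0:
        raise ValueError("true range is empty")
    if n > len(rows):
        raise ValueError(f"n={n} exceeds {len(rows)} available range cells")
    weights = vs.true_suitability.values[rows, cols]
    weights = np.where(np.isnan(weights), 0.0, weights)
    if weights.sum() <= 0:
        weights = np.ones_like(weights)
    probs = weights / weights.sum()
    idx = rng.choice(len(rows), size=n, replace=False, p=probs)
    idx.sort()
    return _cells_to_points(tr, rows[idx], cols[idx], "presence")


def sample_true_absences(vs: VirtualSpecies, n: int, buffer_cells: float,
                         seed: int) -> OccurrenceSet:
    """Draw ``n`` absence points at distinct cell centers whose distance to
    the nearest true-range cell exceeds ``buffer_cells`` (cell units)."""
    rng = np.random.default_rng(seed)
    tr = vs.true_range
    inside = tr.values == 1
    # Euclidean distance (in cells) from every cell to the nearest range cell
    dist = ndimage.distance_transform_edt(~inside)
    eligible = (dist > buffer_cells) & tr.valid_mask
    rows, cols = np.nonzero(eligible)
    if n > len(rows):
        raise ValueError(
            f"n={n} exceeds {len(rows)} cells outside the range + {buffer_cells}-cell buffer")
    idx = rng.choice(len(rows), size=n, replace=False)
    idx.sort()
    return _cells_to_points(tr, rows[idx], cols[idx], "absence")
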