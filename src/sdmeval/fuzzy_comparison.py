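"""Fuzzy global matching (FGM) between two categorical maps.

A cell may partially match nearby cells' categories: the membership of
category ``c`` at cell ``i`` is the maximum, over cells ``j`` of category
``c`` within ``neighborhood_radius`` (Euclidean center-to-center distance
in cell units), of the decay ``2 ** (-dist(i, j) / halving_distance)``;
a cell contributes membership 1 for its own category.  The two-way
similarity at a cell is the minimum of the two directed similarities
(crisp category of one map looked up in the fuzzified other), and the
global index is the arithmetic mean over jointly valid cells.

Defaults (radius 4 cells, halving distance 2 cells, exponential-of-two
decay) follow the documented fuzziness-of-location defaults of the Map
Comparison Kit; radius 0 degenerates to crisp cell-by-cell agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from sdmeval.rasters_io import CategoricalMap, GridRaster


@dataclass
class FuzzyConfig:
    neighborhood_radius: int = 4
    halving_distance: float = 2.0
    distance_metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.neighborhood_radius < 0:
            raise ValueError("neighborhood_radius must be >= 0")
        if not self.halving_distance > 0:
            raise ValueError("halving_distance must be > 0")
        if self.distance_metric != "euclidean":
            raise ValueError("only euclidean distance is supported")

    def offsets(self):
        """(dr, dc, weight) for every neighborhood offset within radius."""
        r = self.neighborhood_radius
        out = []
        for dr in range(-r, r + 1):
            for dc in range(-r, r + 1):
                d = np.hypot(dr, dc)
                if d <= r:
                    out.append((dr, dc, 2.0 ** (-d / self.halving_distance)))
        # sort by descending weight so the first hit is the max
        out.sort(key=lambda t: -t[2])
        return out


def _shift(arr: np.ndarray, dr: int, dc: int, fill) -> np.ndarray:
    """Shift a 2-D array by (dr, dc), filling exposed edges (no wrap)."""
    out = np.full_like(arr, fill)
    rows, cols = arr.shape
    if abs(dr) >= rows or abs(dc) >= cols:
        return out
    rs_src = slice(max(0, -dr), min(rows, rows - dr))
    cs_src = slice(max(0, -dc), min(cols, cols - dc))
    rs_dst = slice(max(0, dr), min(rows, rows + dr))
    cs_dst = slice(max(0, dc), min(cols, cols + dc))
    out[rs_dst, cs_dst] = arr[rs_src, cs_src]
    return out


def fuzzify(m: CategoricalMap, cfg: FuzzyConfig) -> dict[int, np.ndarray]:
    """Per-category fuzzy membership fields of a categorical map.

    Returns ``{category: 2-D membership array}``; nodata cells contribute
    nothing to their neighbors and receive membership 0 everywhere
    (callers mask them out).  Neighborhoods are truncated at map edges.
    """
    memberships: dict[int, np.ndarray] = {}
    offsets = cfg.offsets()
    for cat in sorted(m.valid_categories):
        is_cat = (m.values == cat)
        best = np.zeros(m.shape)
        for dr, dc, w in offsets:
            if w <= best.min() and best.min() > 0:
                break  # remaining offsets cannot raise any cell's maximum
            contrib = _shift(is_cat, dr, dc, False)
            best = np.where(contrib & (w > best), w, best)
        best[~m.valid_mask] = 0.0
        memberships[cat] = best
    return memberships


def fgm(a: CategoricalMap, b: CategoricalMap, cfg: FuzzyConfig | None = None):
    """Fuzzy global matching of two aligned categorical maps.

    Returns ``(value, per_cell)`` where ``value`` is the mean over
    jointly valid cells of ``min(s_AB, s_BA)`` — ``s_AB`` being the
    membership, in fuzzified A, of B's crisp category at that cell —
    and ``per_cell`` is the similarity raster (NaN outside the joint
    valid mask).  Symmetric; equals 1 exactly iff the maps agree
    everywhere; radius 0 reduces to the crisp agreement proportion.
    """
    cfg = cfg or FuzzyConfig()
    if not a.georef_matches(b):
        raise ValueError("maps are not aligned")
    if not (a.valid_categories & b.valid_categories):
        raise ValueError("maps share no categories")
    cats = a.valid_categories | b.valid_categories
    both = a.valid_mask & b.valid_mask
    if not both.any():
        raise ValueError("maps share no valid cells")

    fa = fuzzify(a, FuzzyConfig(cfg.neighborhood_radius, cfg.halving_distance))
    fb = fuzzify(b, FuzzyConfig(cfg.neighborhood_radius, cfg.halving_distance))
    zeros = np.zeros(a.shape)
    s_ab = np.zeros(a.shape)  # B's category looked up in fuzzified A
    s_ba = np.zeros(a.shape)
    for cat in sorted(cats):
        s_ab = np.where(b.values == cat, fa.get(cat, zeros), s_ab)
        s_ba = np.where(a.values == cat, fb.get(cat, zeros), s_ba)
    per_cell = np.minimum(s_ab, s_ba)
    per_cell = np.where(both, per_cell, np.nan)
    value = float(np.nanmean(per_cell))
    raster = GridRaster(values=per_cell, x_origin=a.x_origin, y_origin=a.y_origin,
                        cell_size=a.cell_size, crs_label=a.crs_label)
    return value, raster
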