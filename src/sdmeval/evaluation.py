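"""Binarization, confusion-matrix accuracy indices, AUC, per-category
comparison maps and percentage indices.

Conventions fixed here (the literature leaves both open):

* binarization rule is ``score >= threshold => presence`` (closed at the
  threshold);
* two under-/over-prediction-rate conventions are available:
  ``barbosa`` — UPR = FN/(FN+TN), the proportion of observed presences in
  the predicted-absence *area*; ``complement`` — UPR = FN/(TP+FN) = 1 -
  sensitivity.  OPR = FP/(TP+FP) under both.  Default is ``barbosa``.

Undefined metrics (zero denominator) propagate as NaN markers, never 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from sdmeval.rasters_io import CategoricalMap, GridRaster, OccurrenceSet

logger = logging.getLogger(__name__)

UNDEFINED = math.nan  # explicit marker for zero-denominator metrics

#: comparison-map category codes
BOTH_ABSENT, AGREEMENT, OMISSION, COMMISSION = 0, 1, 2, 3


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.total == 0:
            raise ValueError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsRecord:
    """One model variant's full index suite."""

    model_id: str
    threshold: float = UNDEFINED
    sensitivity: float = UNDEFINED
    specificity: float = UNDEFINED
    tss: float = UNDEFINED
    auc: float = UNDEFINED
    upr: float = UNDEFINED
    opr: float = UNDEFINED
    fgm: float = UNDEFINED
    counts: ConfusionCounts | None = None
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "model_id": self.model_id, "threshold": self.threshold,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "tss": self.tss, "auc": self.auc, "upr": self.upr,
            "opr": self.opr, "fgm": self.fgm,
        }
        d.update(self.extras)
        return d


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else UNDEFINED


def select_threshold(presence_scores, absence_scores) -> float:
    """Threshold maximizing sensitivity + specificity (Youden's J).

    Candidates are the sorted unique scores; classification rule is
    ``score >= t => presence``; ties in J break toward the smallest
    qualifying threshold.  If every score is identical a warning is
    logged and that value returned.
    """
    p = np.asarray(presence_scores, dtype=float)
    a = np.asarray(absence_scores, dtype=float)
    if p.size == 0 or a.size == 0:
        raise ValueError("both presence and absence scores are required")
    candidates = np.unique(np.concatenate([p, a]))
    if candidates.size == 1:
        logger.warning("select_threshold: all scores identical (%.6g)", candidates[0])
        return float(candidates[0])
    # sens(t) = P(p >= t), spec(t) = P(a < t); vectorized over candidates
    sens = (p[:, None] >= candidates[None, :]).mean(axis=0)
    spec = (a[:, None] < candidates[None, :]).mean(axis=0)
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax returns the first (smallest) maximizer
    if j[best] <= 0:
        logger.warning("select_threshold: best Youden's J = %.4f <= 0 "
                       "(scores discriminate no better than random)", j[best])
    return float(candidates[best])


def binarize(s: GridRaster, t: float) -> CategoricalMap:
    """Convert a suitability raster to a binary map: 1 iff score >= t."""
    values = np.where(s.values >= t, 1, 0)
    values = np.where(np.isnan(s.values), -1, values)
    return CategoricalMap(values=values, x_origin=s.x_origin, y_origin=s.y_origin,
                          cell_size=s.cell_size, crs_label=s.crs_label)


def confusion_from_points(pred: CategoricalMap, pts: OccurrenceSet) -> ConfusionCounts:
    """Confusion counts from point records looked up on a binary map."""
    xy = pts.xy
    inside = pred.in_extent(xy[:, 0], xy[:, 1])
    if not inside.all():
        raise ValueError(f"{int((~inside).sum())} point(s) outside the map extent")
    rows, cols = pred.cell_of(xy[:, 0], xy[:, 1])
    cell = pred.values[rows, cols]
    valid = cell != pred.nodata_code
    is_pres = (pts.table["label"] == "presence").to_numpy()
    tp = int(((cell == 1) & is_pres & valid).sum())
    fp = int(((cell == 1) & ~is_pres & valid).sum())
    fn = int(((cell == 0) & is_pres & valid).sum())
    tn = int(((cell == 0) & ~is_pres & valid).sum())
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def confusion_from_maps(pred: CategoricalMap, ref: CategoricalMap) -> ConfusionCounts:
    """Cell-by-cell confusion counts of a binary prediction vs a binary
    reference map, over jointly valid cells."""
    if not pred.georef_matches(ref):
        raise ValueError("prediction and reference grids are not aligned")
    both = pred.valid_mask & ref.valid_mask
    p = pred.values[both]
    r = ref.values[both]
    return ConfusionCounts(
        tp=int(((p == 1) & (r == 1)).sum()),
        fp=int(((p == 1) & (r == 0)).sum()),
        fn=int(((p == 0) & (r == 1)).sum()),
        tn=int(((p == 0) & (r == 0)).sum()),
    )


def compute_metrics(c: ConfusionCounts, convention: str = "barbosa") -> dict:
    """Sensitivity, specificity, TSS and under-/over-prediction rates.

    ``convention`` picks the UPR denominator: ``barbosa`` = FN/(FN+TN),
    ``complement`` = FN/(TP+FN).  OPR = FP/(TP+FP) in both.
    """
    if convention not in ("barbosa", "complement"):
        raise ValueError(f"unknown UPR convention {convention!r}")
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    tss = sens + spec - 1.0  # NaN-propagating
    opr = _ratio(c.fp, c.tp + c.fp)
    if convention == "barbosa":
        upr = _ratio(c.fn, c.fn + c.tn)
    else:
        upr = _ratio(c.fn, c.tp + c.fn)
    return {"sensitivity": sens, "specificity": spec, "tss": tss,
            "upr": upr, "opr": opr}


def compute_auc(presence_scores, absence_scores) -> float:
    """Rank-sum (Mann-Whitney) AUC with midranks for ties."""
    p = np.asarray(presence_scores, dtype=float)
    a = np.asarray(absence_scores, dtype=float)
    if p.size == 0 or a.size == 0:
        raise ValueError("both presence and absence scores are required")
    ranks = rankdata(np.concatenate([p, a]))
    rank_sum = ranks[: p.size].sum()
    u = rank_sum - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * a.size))


def compare_per_category(pred: CategoricalMap, ref: CategoricalMap):
    """Per-category cell-by-cell comparison map.

    Codes: 0 both-absent, 1 agreement (both present), 2 omission
    (reference present, prediction absent), 3 commission (prediction
    present, reference absent).  Returns ``(map, counts_per_code)``.
    """
    if not pred.georef_matches(ref):
        raise ValueError("prediction and reference grids are not aligned")
    both = pred.valid_mask & ref.valid_mask
    p = pred.values
    r = ref.values
    out = np.full(pred.shape, -1, dtype=np.int64)
    out[both & (p == 0) & (r == 0)] = BOTH_ABSENT
    out[both & (p == 1) & (r == 1)] = AGREEMENT
    out[both & (p == 0) & (r == 1)] = OMISSION
    out[both & (p == 1) & (r == 0)] = COMMISSION
    cmap = CategoricalMap(values=out, x_origin=pred.x_origin, y_origin=pred.y_origin,
                          cell_size=pred.cell_size,
                          valid_categories=frozenset({0, 1, 2, 3}))
    counts = {code: int((out == code).sum())
              for code in (BOTH_ABSENT, AGREEMENT, OMISSION, COMMISSION)}
    return cmap, counts


def percentage_indices(c: ConfusionCounts, convention: str = "barbosa") -> dict:
    """The metric suite expressed as percentages, plus overall agreement
    100*(TP+TN)/N (a clearly-labelled substitute for 'total cells
    detected', which has no printed definition)."""
    m = compute_metrics(c, convention=convention)
    return {
        "sensitivity_pct": 100.0 * m["sensitivity"],
        "specificity_pct": 100.0 * m["specificity"],
        "opr_pct": 100.0 * m["opr"],
        "upr_pct": 100.0 * m["upr"],
        "agreement_pct": 100.0 * (c.tp + c.tn) / c.total,
    }
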