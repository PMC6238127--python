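"""End-to-end orchestration: run a model x predictor-set ensemble on a
world with known truth, assemble the accuracy-index table, and correlate
fuzzy global matching with the discrimination measures."""

from __future__ import annotations

import itertools
import json
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from sdmeval import evaluation, fuzzy_comparison, sdm_algorithms, synthetic_world
from sdmeval.rasters_io import (CategoricalMap, EnvStack, GridRaster,
                                OccurrenceSet, extract_values, write_raster)

logger = logging.getLogger(__name__)


@dataclass
class VariantSpec:
    """One ensemble member: an algorithm on a predictor subset."""

    model_id: str
    algorithm: str                       # bioclim | domain | glm | import | oracle
    layer_names: list[str] = field(default_factory=list)
    threshold: str | float = "auto"      # "auto" = Youden-optimal on the sample points
    raster: GridRaster | None = None     # for algorithm == "import"
    rescale: bool = False

    def __post_init__(self) -> None:
        if self.algorithm not in ("bioclim", "domain", "glm", "import", "oracle"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.algorithm == "import" and self.raster is None:
            raise ValueError("import variants need a raster")


@dataclass
class EnsembleSpec:
    variants: list[VariantSpec]
    fuzzy: fuzzy_comparison.FuzzyConfig = field(
        default_factory=fuzzy_comparison.FuzzyConfig)
    upr_convention: str = "barbosa"
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [v.model_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant model_ids")


def _scores_at_points(suit: GridRaster, pts: OccurrenceSet) -> np.ndarray:
    rows, cols = suit.cell_of(pts.xy[:, 0], pts.xy[:, 1])
    return suit.values[rows, cols]


def _fit_predict(variant: VariantSpec, stack: EnvStack, train: pd.DataFrame,
                 reference: CategoricalMap) -> GridRaster:
    names = variant.layer_names or stack.names
    if variant.algorithm == "bioclim":
        m = sdm_algorithms.fit_bioclim(train[train["label"] == "presence"], names)
        return sdm_algorithms.predict_bioclim(m, stack)
    if variant.algorithm == "domain":
        m = sdm_algorithms.fit_domain(train[train["label"] == "presence"], names)
        return sdm_algorithms.predict_domain(m, stack)
    if variant.algorithm == "glm":
        m = sdm_algorithms.fit_glm(train, names)
        return sdm_algorithms.predict_glm(m, stack)
    if variant.algorithm == "import":
        return sdm_algorithms.import_prediction(variant.raster, stack.template,
                                                rescale=variant.rescale)
    # oracle: feed the reference map back as a perfect 0/1 suitability surface
    vals = np.where(reference.valid_mask, reference.values.astype(float), np.nan)
    return GridRaster(values=vals, x_origin=reference.x_origin,
                      y_origin=reference.y_origin, cell_size=reference.cell_size)


def run_ensemble(stack: EnvStack, reference: CategoricalMap,
                 presences: OccurrenceSet, absences: OccurrenceSet,
                 spec: EnsembleSpec):
    """Fit, threshold, binarize and score every ensemble variant.

    Each variant is compared cell-by-cell and fuzzily against the
    ``reference`` binary map (the true range in synthetic runs, an
    expert-delimited map otherwise).  Variant failures are logged and
    isolated; the rest of the ensemble proceeds.

    Returns ``(table, artifacts)``: a tidy metrics DataFrame with one row
    per surviving variant, and per-variant comparison/similarity rasters.
    """
    train = extract_values(stack, OccurrenceSet(
        pd.concat([presences.table, absences.table], ignore_index=True)))
    train = train[train["valid"]].reset_index(drop=True)

    rows = []
    artifacts: dict[str, dict] = {}
    for variant in spec.variants:
        try:
            suit = _fit_predict(variant, stack, train, reference)
            p_scores = _scores_at_points(suit, presences)
            a_scores = _scores_at_points(suit, absences)
            ok_p = ~np.isnan(p_scores)
            ok_a = ~np.isnan(a_scores)
            p_scores, a_scores = p_scores[ok_p], a_scores[ok_a]
            if variant.threshold == "auto":
                thr = evaluation.select_threshold(p_scores, a_scores)
            else:
                thr = float(variant.threshold)
            binary = evaluation.binarize(suit, thr)
            counts = evaluation.confusion_from_maps(binary, reference)
            metrics = evaluation.compute_metrics(counts, convention=spec.upr_convention)
            auc = evaluation.compute_auc(p_scores, a_scores)
            comparison, category_counts = evaluation.compare_per_category(binary, reference)
            fgm_value, similarity = fuzzy_comparison.fgm(binary, reference, spec.fuzzy)
            pct = evaluation.percentage_indices(counts, convention=spec.upr_convention)
            record = evaluation.MetricsRecord(
                model_id=variant.model_id, threshold=thr, auc=auc,
                fgm=fgm_value, counts=counts, extras=pct, **metrics)
            rows.append(record.as_dict())
            artifacts[variant.model_id] = {
                "suitability": suit, "binary": binary, "comparison": comparison,
                "similarity": similarity, "category_counts": category_counts,
            }
        except Exception:
            logger.exception("variant %r failed; continuing with the rest",
                             variant.model_id)
    if not rows:
        raise RuntimeError("every ensemble variant failed")
    return pd.DataFrame(rows), artifacts


# ---------------------------------------------------------------------------
# rank correlation
# ---------------------------------------------------------------------------

_EXACT_N = 9


def spearman(x, y) -> tuple[float, float]:
    """Midrank Spearman rho with a two-sided p-value.

    p is computed from the exact permutation distribution for n <= 9 and
    from the t approximation ``t = rho * sqrt((n-2) / (1-rho^2))`` with
    n - 2 degrees of freedom otherwise.  Zero variance in either vector
    yields ``(nan, nan)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("spearman: zero variance; correlation undefined")
        return (math.nan, math.nan)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    def _rho(a, b):
        a = a - a.mean(axis=-1, keepdims=True)
        b = b - b.mean(axis=-1, keepdims=True)
        return (a * b).sum(axis=-1) / np.sqrt(
            (a ** 2).sum(axis=-1) * (b ** 2).sum(axis=-1))

    rho = float(_rho(rx, ry))
    if n <= _EXACT_N:
        perms = np.array(list(itertools.permutations(ry)))
        rho_perm = _rho(np.broadcast_to(rx, perms.shape), perms)
        p = float((np.abs(rho_perm) >= abs(rho) - 1e-12).mean())
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho ** 2))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, p


_CORRELATED_METRICS = ["sensitivity", "specificity", "upr", "opr", "auc", "tss"]


def correlate_fgm(table: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of the FGM column against each accuracy index.

    One row per metric: (metric, rho, p, n).  Requires >= 3 variants;
    a constant FGM column makes every row undefined (with a warning).
    """
    if len(table) < 3:
        raise ValueError("rank correlation needs at least 3 ensemble variants")
    rows = []
    for metric in _CORRELATED_METRICS:
        ok = table[[metric, "fgm"]].notna().all(axis=1)
        sub = table[ok]
        if len(sub) < 3:
            rho, p = math.nan, math.nan
        else:
            rho, p = spearman(sub["fgm"].to_numpy(), sub[metric].to_numpy())
        rows.append({"metric": metric, "rho": rho, "p": p, "n": int(ok.sum())})
    return pd.DataFrame(rows)


def report(table: pd.DataFrame, correlations: pd.DataFrame | None,
           out_dir: str, artifacts: dict | None = None,
           config: dict | None = None) -> dict:
    """Write the metrics table, correlation table, per-variant rasters and
    a run manifest to ``out_dir``; returns the manifest dict."""
    os.makedirs(out_dir, exist_ok=True)
    metrics_path = os.path.join(out_dir, "metrics.csv")
    table.to_csv(metrics_path, index=False, float_format="%.10g")
    written = [metrics_path]

    if correlations is not None and len(table) >= 3:
        corr_path = os.path.join(out_dir, "correlations.csv")
        correlations.to_csv(corr_path, index=False, float_format="%.10g")
        written.append(corr_path)
    elif correlations is None:
        logger.info("report: correlation stage skipped (fewer than 3 variants)")

    for model_id, art in (artifacts or {}).items():
        for key in ("comparison", "similarity"):
            path = os.path.join(out_dir, f"{model_id}_{key}.tif")
            write_raster(art[key], path, format="geotiff")
            written.append(path)

    import sdmeval
    manifest = {
        "config": config or {},
        "version": sdmeval.__version__,
        "n_variants": int(len(table)),
        "files": [os.path.basename(p) for p in written],
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# default synthetic experiment
# ---------------------------------------------------------------------------

#: true-model coefficients for the default world (intercept first)
DEFAULT_BETA = (-0.5, 2.0, -1.5, 1.0, 0.8)
DEFAULT_CUTOFF = 0.5
DEFAULT_N_PRESENCES = 100
DEFAULT_N_ABSENCES = 1000
DEFAULT_ABSENCE_BUFFER = 2.0


def default_world(seed: int = 0, n_rows: int = 100, n_cols: int = 100,
                  satellites: bool = False,
                  n_presences: int = DEFAULT_N_PRESENCES,
                  n_absences: int = DEFAULT_N_ABSENCES):
    """Build the default seeded virtual-species experiment.

    100 x 100 world, 4 autocorrelated standardized predictors, a strong
    logistic truth, 100 presences and 1,000 true absences sampled outside
    a 2-cell buffer around the range.

    Returns ``(stack, species, presences, absences)``.
    """
    cfg = synthetic_world.WorldConfig(n_rows=n_rows, n_cols=n_cols,
                                      n_predictors=4, autocorr_length=5.0,
                                      seed=seed)
    stack = synthetic_world.generate_predictors(cfg)
    sat = [(n_rows - 10, n_cols - 10, 3)] if satellites else []
    species = synthetic_world.define_species(stack, DEFAULT_BETA, DEFAULT_CUTOFF,
                                             satellite_spec=sat)
    presences = synthetic_world.sample_presences(species, n_presences,
                                                 seed=seed + 1)
    absences = synthetic_world.sample_true_absences(species, n_absences,
                                                    DEFAULT_ABSENCE_BUFFER,
                                                    seed=seed + 2)
    return stack, species, presences, absences


def default_ensemble_spec(stack: EnvStack, seed: int = 0) -> EnsembleSpec:
    """The default model x predictor-set ensemble.

    Spans restrictive (envelope) to permissive (low fixed-threshold
    similarity) variants on the full and a reduced predictor set.
    """
    names = stack.names
    few = names[:2]
    variants = [
        VariantSpec("bioclim_all", "bioclim", names),
        VariantSpec("bioclim_few", "bioclim", few),
        VariantSpec("domain_all", "domain", names),
        VariantSpec("domain_low", "domain", names, threshold=0.05),
        VariantSpec("glm_all", "glm", names),
        VariantSpec("glm_few", "glm", few),
    ]
    return EnsembleSpec(variants=variants, seed=seed)
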