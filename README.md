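# sdmeval

Species distribution modelling, categorical map comparison and accuracy
evaluation — built around a virtual-species simulator so the entire
pipeline can be exercised with full ground truth and no external data.

What's inside:

- **`rasters_io`** — grid/point data model; GeoTIFF (via `tifffile` with
  GDAL-compatible georeference tags) and ESRI ASCII grid I/O; occurrence
  CSVs; value extraction at points.
- **`synthetic_world`** — spatially autocorrelated predictor stacks with
  controllable collinearity, a logistic true-suitability surface with a
  known range (optionally with disjunct satellite patches), and seeded
  presence / true-absence samplers.
- **`study_design`** — range-map construction by buffering peripheral
  presences (two-tier buffers with an "abrupt change" mask), seeded
  minimum-distance thinning, random subsetting, and greedy Spearman-based
  predictor selection (|rho| < 0.7 by default).
- **`sdm_algorithms`** — from-scratch suitability models: a climate
  envelope scored by two-tailed empirical percentiles, a
  nearest-record Gower-similarity model, and a binomial GLM fitted by
  IRLS — plus an importer for externally produced suitability rasters.
- **`evaluation`** — sensitivity/specificity-optimal (Youden) threshold
  selection, binarization, confusion matrices from points or maps,
  sensitivity / specificity / TSS / AUC / under- and over-prediction
  rates (two UPR conventions), per-category comparison maps and
  percentage indices.
- **`fuzzy_comparison`** — fuzzy global matching (FGM) between
  categorical maps with distance-decayed neighborhood membership
  (`2^(-d/halving)`, radius 4 / halving 2 defaults), verified against a
  brute-force oracle.
- **`analysis_pipeline`** — ensemble orchestration (algorithm x
  predictor-set variants), the metrics table, and Spearman correlation
  of FGM with each accuracy index (exact permutation p-values for small
  n).

## Tests

```
python -m pytest -q
```

The suite includes property tests (hypothesis), brute-force oracle
cross-checks for FGM / AUC / threshold selection / the envelope and
similarity models, and `tests/test_acceptance.py` with the end-to-end
acceptance criteria. Everything runs in well under a minute.

## CLI

```
sdmeval simulate --config world.yaml --seed 1 --out world/
sdmeval design   --presences pts.csv --grid grid.tif --stack world/ --out design/
sdmeval fit      --algo glm --stack world/ --presences p.csv --absences a.csv --out suit.tif
sdmeval evaluate --pred suit.tif --ref range.tif --presences p.csv --absences a.csv --out eval/
sdmeval compare  --map-a pred.tif --map-b range.tif --radius 4 --halving 2
sdmeval run      --config run.yaml --seed 1 --out results/
```

`run` executes the full synthetic experiment: simulate a world, fit the
default six-variant ensemble (envelope / similarity / GLM on full and
reduced predictor sets, plus a permissive low-threshold similarity
variant), score every variant against the true range (cell-by-cell and
fuzzily), and correlate FGM with the accuracy indices.

Binarization uses the rule `score >= threshold => presence`; the
threshold maximizes sensitivity + specificity unless given explicitly.

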