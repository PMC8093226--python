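# histotyping

Quantitative gland-lumen morphometry and penalized Cox survival modeling
for prognosis of biochemical recurrence (BCR) after radical prostatectomy,
from a single annotated H&E tumor region.

After prostate removal, a rising serum PSA (two tests > 0.2 ng/mL) marks
biochemical recurrence. Pathologist-assigned Gleason grade predicts BCR
but is subjective; molecular classifiers are tissue-destructive and
expensive. This package implements the alternative: computer-extracted
features of gland lumen shape and arrangement from a routine H&E slide,
combined into a risk score by a penalized Cox model. It is aimed at
computational-pathology researchers who want a fully testable, synthetic-
data-backed reference implementation of that pipeline.

## The pipeline

1. **Segmentation** (`segmentation`) — the tumor-region image is resampled
   to 1 µm/px and gland lumens (near-white, unstained) are segmented by a
   classical low-stain/high-luminance pipeline with a pluggable interface;
   precomputed label masks can be supplied instead.
2. **Features** (`shape_features`, `graph_texture_features`) — a fixed
   242-feature catalog per region: 96 lumen-shape features (Fourier
   descriptors of the centroid-distance signal, Hu invariant moments,
   radius/contour ratios × {mean, SD, median, p5/p95}), 52 architecture
   features (Voronoi/Delaunay/MST/nearest-neighbor/density statistics on
   lumen centroids), 68 sub-graph features (connected components of an
   ε-neighborhood graph), and 26 Haralick texture features (13 GLCM
   statistics × mean/range over 4 directions).
3. **Stability filtering** (`stability_batch`) — features whose
   distributions on benign regions differ between contributing sites
   (max pairwise two-sample KS > 0.4) are dropped before training, and a
   UMAP audit contrasts site clustering in image-quality metrics (29 per
   image) against the model's feature space.
4. **Risk model** (`survival_model`) — features are z-normalized on the
   training set and fit with an elastic-net penalized Cox model
   (α = 0.5, λ by 10-fold cross-validated partial-likelihood deviance,
   Breslow ties). The per-SD hazard ratio of feature *x* is e^{β_x}. The
   continuous score is logistic(β·z) ∈ [0, 1]; a threshold maximizing the
   training logrank χ² splits patients into low/high risk. The published
   six-feature model ships ready to use:

   | feature | HR per SD |
   |---|---|
   | `shape:mean:fd3` | 1.002 |
   | `shape:sd:hu1` | 0.932 |
   | `shape:median:distance_ratio` | 1.100 |
   | `shape:p5_p95:fd6` | 0.968 |
   | `shape:p5_p95:fd9` | 0.929 |
   | `subgraph:kurtosis:edge_length` | 0.977 |

5. **Evaluation & robustness** (`evaluation`, `robustness`) — KM curves,
   logrank, hazard ratios, Harrell's c-index with paired bootstrap model
   comparison, multivariable Cox, Bonferroni-corrected subgroup analysis,
   genomic-classifier risk categories (cuts 0.45/0.60), and a boundary-
   erosion experiment that removes outer gland layers and rescores.
6. **Synthetic data** (`synthetic_data`) — pseudo-H&E cohorts with known
   lumen geometry (disk/ellipse/crescent mixtures), site-specific stain
   presets, and Weibull proportional-hazards outcomes driven by generator
   knobs, so every stage is testable without clinical data.

## Worked example

```sh
histotyping simulate --out cohort --n-patients 50 --canvas-um 448 --seed 4 --no-render
# ... extract features (library call or `histotyping features`), then:
histotyping train    --features features.csv --clinical cohort/clinical.csv --out-model model.json --seed 0
histotyping score    --model model.json --features features.csv --out scores.csv
histotyping evaluate --scores scores.csv --clinical cohort/clinical.csv --out report.json --km-plot km.png
```

On this 50-patient synthetic cohort (risk carried by the disk-shaped
lumen fraction) the run prints:

```
model with 7 selected features -> model.json
```

and `report.json` contains

```json
{
  "logrank_p": 1.17e-06,
  "hazard_ratio": 5.99,
  "cindex": 0.719,
  "median_years_to_event": {"low": 6.67, "high": 3.28},
  "n_per_group": {"low": 31, "high": 19}
}
```

i.e. the learned threshold separates the cohort into 31 low-risk and 19
high-risk patients whose BCR-free survival differs strongly (logrank
p ≈ 1e-6, HR ≈ 6); the continuous score ranks patients with concordance
0.72. `histotyping erode`, `filter-stability` and `audit` run the
robustness experiments on the same directory.

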