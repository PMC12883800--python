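# Methods

## Problem setting

The unit of analysis is the forest sub-compartment (FSC): an irregular
inventory polygon, internally homogeneous in vegetation cover type, one of
{Arbor, Shrub, Bamboo, Bare, Other}. Given co-registered multispectral
rasters for two epochs (10 m pixels; bands B2/B3/B4/B8, optionally
B11/B12) and the FSC layer, the pipeline classifies every FSC in each
epoch independently and flags an FSC as changed when its predicted labels
differ — post-classification comparison. This trades temporal modeling for
robustness and interpretability: each epoch's classification can be
validated on its own, and transitions aggregate into a K × K matrix whose
row-normalized diagonal is the per-class retention rate.

## Patch extraction

Each FSC is represented by a single fixed 5 × 5-pixel window centered on
the pixel nearest its geometric centroid (pixel-center registration,
round-half-down on exact ties so windows are bit-reproducible). When the
centroid of a concave polygon falls outside it, a guaranteed-interior
representative point is used instead — the contract that matters is that
the window center lies inside the source polygon, avoiding neighboring-FSC
pixels. Windows crossing the raster edge are skipped with a log entry;
windows touching nodata are excluded rather than imputed, since imputation
would fabricate texture. FSCs above 3,000 m² (strict inequality) are
training-eligible; for them the full window is interior in ≥95% of
generated cases (verified in the test suite via the 25 sampled pixel
centers). Smaller FSCs are retained at prediction time and flagged
out-of-distribution. The labeled, training-eligible samples are split
80/20, stratified by class, deterministically under the run seed; a class
with fewer than two samples stays whole on the training side with a
warning.

## Features

Spectral features are the window band means plus ten vegetation indices
evaluated on those means (NDVI, EVI, NBRI, SAVI, RVI, DVI, NDBI, BGRVI,
GNDVI, NDWI; SAVI with L = 0.5 and the matching 1.5 scaling). Evaluating
on means rather than per pixel is cheaper and deterministic; the two
differ for ratio indices, so a `vi_per_pixel` switch provides the
alternative. A denominator below 1e-12 in magnitude yields 0 with a
degenerate-input flag. BGRVI is implemented exactly as
(B3 − (B2 + B4))/(B3 + (B2 + B4)).

Texture features are the eight GLCM metrics computed on the NIR band (B8)
by default — the band with the strongest vegetation signal; any band list
can be configured. The window is quantized to 32 levels between its own
min and max (half-open bins, constants map to level 0); co-occurrences are
accumulated at distance 1 over the four standard angles, symmetrized and
normalized. The source band, quantization depth, offsets and angle
handling are conventional defaults, config-exposed. Two widely-circulated
variant formulas for VAR (sample-variance-style division by N − 1) and DIS
(an extra leading i factor) describe different quantities than the
contrast/heterogeneity measures they are used as; the standard Haralick
forms are implemented (VAR = Σ(i − μ)²P(i,j), DIS = Σ|i − j|P(i,j)) and
cross-checked against a brute-force pair-enumeration oracle at 1e-10.

## Feature selection

Spectral (bands + indices) and texture features are ranked in two
independent groups, each by total gain (summed loss reduction over all
splits) in an XGBoost classifier trained on that group alone; grouping
prevents the larger spectral family from crowding out texture in a joint
model. Boosting settings are fixed for determinism: 100 trees, depth 4,
learning rate 0.1, histogram method, single thread. Within each group the
selected set is the smallest ranking prefix whose cumulative normalized
gain reaches the threshold (default 0.85, mirroring the cumulative-
contribution practice of selecting the dominant texture metrics). Selection
is monotone in the threshold; constant features get gain 0 and rank last.

## Classifiers

All models consume standardized features and emit probability vectors over
the fixed class order (Arbor, Shrub, Bamboo, Bare, Other); argmax ties
break toward the earlier class. Baselines: random forest (50 trees, max
depth 8, seed 42) and an RBF-kernel SVM (C = 100, gamma = 'scale',
probability outputs).

The BPNN is a two-hidden-layer ReLU network (default 50/50) with softmax
output, trained full-batch with Adam on cross-entropy for 300 epochs; the
per-epoch loss trajectory is recorded. Full-batch training keeps runs
bit-deterministic under a seed.

PSO-BPNN wraps the BPNN in canonical inertia-weight particle swarm
optimization (per-dimension r₁, r₂ ~ U(0,1); v ← w·v + c₁r₁(pbest − x) +
c₂r₂(gbest − x); w linear from 0.9 to 0.4; positions clipped to bounds;
velocities clamped to 20% of each bound's range — a standard stabilization,
config-exposed). Defaults: 50 particles, 100 generations, c₁ = c₂ = 1.5.
Because jointly encoding architecture and weights would give a
variable-length search space, the optimization is two-staged:

1. **Architecture stage** — search (hidden₁, hidden₂, learning rate) in
   (16–128, 16–128, 0.001–0.1); continuous positions round to integer
   layer sizes. Fitness is validation cross-entropy after a short proxy
   training (default 30 epochs) on an internal stratified 80/20 split of
   the training data. The proxy depth is a config knob: long enough to
   rank candidates, far cheaper than full training.
2. **Initialization stage** (can be disabled) — search the flat initial
   weight vector of the winning architecture within ±0.5 per weight
   (comparable to the He-initialization scale for these layer widths),
   same fitness.

The final network trains on all training samples for 300 epochs from the
stage-2 initialization. Non-finite fitness penalizes the particle with +∞
and the run continues; the global best is monotone nonincreasing by
construction and asserted in tests.

## Change detection and evaluation

Labels from the two epochs are compared per FSC (both epochs must cover
the same id set; FSCs unclassifiable in either epoch — masked or edge
windows — are excluded from the matrix and reported separately).
Transition matrices use rows = earlier epoch, columns = later epoch, the
orientation under which the published county table's row sums equal the
survey's per-class totals. Retention and conversion rates are
row-normalized percentages, rounded only at presentation.

Accuracy metrics follow the confusion-matrix definitions with per-class
one-vs-rest precision/recall/F1 reported as unweighted macro averages
(the task has five classes but single summary values are conventional;
weighted averaging is available), plus Cohen's κ = (P₀ − Pₑ)/(1 − Pₑ).
Change-detection skill is the fraction of reference-changed FSCs whose
predicted labels differ (detected + missed = reference count, always).
Spatial clustering of detected changes uses the Clark–Evans NNI on change-
polygon centroids with the standard CSR expectation d̄ₑ = 0.5/√(n/A),
SE = 0.26136/√(n²/A) and a two-sided normal p-value, without edge
correction — the form used by common GIS tooling. The choice of centroids
as the point representation is the natural one for polygon-level changes.

## Synthetic scenes

The generator stands in for inventory data that cannot be redistributed.
It emulates, per epoch:

- **Tessellation** — Voronoi cells of seed points placed on distinct pixel
  centers with a mixed density (left-to-right gradient plus three tight
  clusters), giving a heavy-tailed area distribution from single-pixel
  slivers to cells covering ≥10% of the grid, as in real FSC layers where
  areas span 100 m² to hundreds of thousands of m². Distinct seed pixels
  guarantee every polygon owns at least one pixel; pixel ownership is
  exact nearest-seed assignment, consistent with the vector cells.
- **Spectra** — per-class band-mean signatures in surface reflectance:
  vegetation classes with strong red-edge contrast (B8 ≫ B4), Bare with a
  bright soil spectrum (B4 ≥ B8). Neighboring classes overlap deliberately
  (Arbor/Bamboo close in index ratios, Shrub/Other close spectrally).
- **Brightness** — a scene-wide multiplicative field (Gaussian-smoothed
  white noise, correlation length 10 px, unit variance, redrawn each
  epoch) scales all bands proportionally with per-class gain 0.20–0.30.
  This is the generator's model of terrain illumination and canopy-density
  variation: raw band values swing ±20–30% within a class while ratio
  indices stay nearly constant, which is precisely why index features add
  skill over raw bands on real imagery.
- **Texture** — per-class additive noise fields smoothed at the class's
  correlation length (Arbor 2.5 px smooth canopy → Bare 0.4 px fine
  grain), rescaled to the class's pixel standard deviation, giving classes
  distinct co-occurrence statistics without a heavier texture model.
- **Changes** — exactly round(change_fraction × n_fsc) FSCs, drawn
  uniformly among those above 3,000 m² (so every injected change is
  learnable under the training filter), relabeled uniformly to one of the
  other four classes.
- **Class composition** — default proportions follow the rebalanced
  training composition (43.9/40.0/14.0/0.7/1.4%), not the raw inventory
  (~94% Arbor); the rare classes (Bare, Other) remain genuinely rare,
  which is the main driver of missed changes.

Default noise levels were fixed once to put the ablation in a realistic
regime (band-only accuracy ~0.90, +indices ~0.94, +texture ~0.97 with an
RF on ~950 training FSCs) rather than at saturation. What the generator
does **not** emulate: atmospheric and phenological variation, mixed pixels
at 20 m→10 m resampling, topographic shadow geometry, spatially clustered
(disturbance-driven) change, and label noise in the survey itself. Passing
tests therefore demonstrate the pipeline's correctness and its behavior
under the assumed statistical structure, not field-accuracy on real
imagery.

## Problem sizes and numerical choices

The acceptance script and end-to-end tests run the pipeline on a 352 × 352
grid with 2,000 FSCs (~950 training-eligible) and 5% injected change, with
PSO at 10 particles × 12 generations and 25 proxy epochs — sizes chosen to
exercise every stage at meaningful sample counts while keeping a full run
in tens of seconds; the optimizer's library defaults remain the full
50 × 100 configuration. The feature-ablation comparison uses the
random-forest classifier over 10 paired seeds. Determinism: every
stochastic component (tessellation, noise, splits, boosting, network
initialization, PSO) draws from seeds derived from the run seed; reruns
are byte-identical. Degenerate inputs are contracts, not crashes: constant
windows quantize to level 0, zero-variance GLCM marginals give COR = 0
with a flag, empty transition rows raise a typed degenerate-input error,
never-predicted classes get precision 0 with a flag.

## Known limitations

- Post-classification comparison compounds per-epoch errors; with
  per-epoch accuracy p, the chance of a truly-changed FSC being detected
  is bounded near p² when errors are independent, so detection rates track
  classification accuracy quadratically.
- Rare classes (<1% of training data) are frequently absorbed into their
  spectrally nearest neighbor; changes *into* such classes dominate the
  missed set, mirroring the behavior reported for small or rare-type FSCs
  in operational use.
- The NNI uses no edge correction; for patterns with many points near the
  study-area boundary it is biased upward.
- Reading arbitrary third-party GeoTIFFs is limited to the package's own
  metadata convention (JSON band names + GeoTIFF georeferencing tags);
  Shapefile input is not supported — GeoJSON is the vector interchange.
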