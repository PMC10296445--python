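# Methods

## Problem and model

Each Visium-style slide provides a spots × genes count matrix and per-spot
`(x, y)` coordinates in arbitrary slide units (spots on the synthetic grid
are 2 units apart; real platforms use their own units, which are taken
as-is — no flipping or rescaling on read). The model is a dense feedforward
regressor from a spot's normalized expression vector to its coordinates.
Each hidden block is `dense → batch-norm → ReLU`; the output layer is a
linear `dense(2)`. Hidden widths follow a halving geometric series whose
*total* is as close as possible to half the input size: with L layers the
first width is `w1 = n_input / (2 Σ_{j<L} 2^{-j})` and layer j gets
`round(w1 / 2^j)`, each width rounded from the unrounded `w1` so the total
stays nearest the budget (e.g. 1000 inputs, 3 layers → 286/143/71). An
alternative reading — first hidden layer = half the input, then halving —
is available via `first_layer_half=True`. Widths below 2 or non-decreasing
sequences raise an error.

Training minimizes the mean distance error (MDE), the mean Euclidean
distance between predicted and actual coordinates, which is also the
reported metric. Coordinates are regressed in raw slide units (no target
standardization), so MDE numbers are directly interpretable as distances on
the slide.

## Cross-validation design

Spots are randomized once per seed into k = 10 folds. Every fold is the
test fold exactly once; its validation fold is `(i + 1) mod k` (a fixed,
reproducible pairing) and the remaining k − 2 folds train. The grid —
hidden layers ∈ {1, 3, 5} × learning rate ∈ {0.1, 0.01, 0.001} by default —
is scored by the MDE of the aggregated test-fold predictions; ties prefer
fewer layers, then a smaller learning rate. The winning grid point's k
within-fold models are kept: they are the attribution models, ensuring no
spot is ever attributed by a model that trained on it.

Model skill is always reported against the *centroid null*, the MDE of
predicting every spot at the mean coordinate (≈ 0.38 × the slide side for a
uniform square).

## Numerical choices

The network, optimizer and attribution are implemented in numpy; the models
are small (hundreds of units), so explicit passes are fast and the whole
pipeline is bit-reproducible for a fixed seed.

* He-normal initialization, `std = sqrt(2 / fan_in)`, for all dense layers.
* Adam with β₁ = 0.9, β₂ = 0.999, ε = 1e-7.
* Batch-norm: ε = 1e-3; running-statistic momentum 0.9, so inference-mode
  statistics track the data within a few epochs — necessary because the
  early-stopping monitor (validation MDE) is measured in inference mode.
* Early stopping: patience 10 epochs on validation MDE, best weights
  restored; batch size 32; at most 100 epochs.
* The MDE gradient at a perfectly predicted spot (distance 0) is taken as 0.
* Per-(grid point, fold) model seeds derive from the user seed via
  `SeedSequence`, keeping runs independent but reproducible.

## Attribution

DeepLIFT with the Rescale rule, applied to the network in inference form:
batch-norm is folded into its affine scale/shift, leaving a chain of affine
maps and ReLUs. Multipliers start at the scalar target — by default
`t = x′ + y′`, the sum of the two outputs; per-axis targets are available
and the mode is recorded — and propagate through affine layers by their
weights and through each ReLU by the secant slope
`(relu(u) − relu(u0)) / (u − u0)`, falling back to the local derivative when
the denominator is below 1e-9. Contributions are `m_input · (x − x0)` with
an all-zeros reference `x0` (after per-gene standardization, zero is the
per-gene mean). Both propagation rules conserve `Σ multiplier · Δ`, so the
completeness identity `Σ_g C_gs = t − t0` holds to float precision; the
stored matrices are checked at relative tolerance 1e-3 (absolute floor
1e-6).

## Preprocessing

Order: spot filter → gene filter → normalize → variance filter. Counts are
required for the count-based rules (a normalized slide is rejected): spots
need ≥ 200 detected genes; genes need ≥ 10 total reads *and* detection in
≥ 2 spots. Normalization is log1p-CPM (library size 10,000) with optional
per-gene centering/unit-variance scaling (default on; zero-variance genes
map to 0). A variance-stabilizing regression model such as SCTransform is
*not* reimplemented — the network only needs a stabilized input
representation, and the transform is a config choice. The variance filter
(< 0.05, strict) runs on the normalized representation immediately before
training and uses the population variance (ddof = 0) throughout; with
per-gene scaling on, it removes exactly the zero-variance genes. On
synthetic panels much smaller than a transcriptome the spot threshold is
scaled to half the panel size, since "200 detected genes" presumes
genome-wide capture.

## Importance statistics and the SPG call

Per slide: `MeanImp_g` = mean of `|C_gs|` over all spots; `MNI_g` = mean
over the n₀ spots with importance strictly above a zero tolerance (default
exactly 0; `MNI = 0` when n₀ = 0); `PNI_g = 100 n₀ / n` with n all spots in
the slide. Cross-slide scores (CSMI, CSMNI, CSPNI) are unweighted means
over the patient's slides; slides with differing gene sets are intersected
with a warning. A median (or sum) aggregation mode exists for sensitivity
checks; mean is the default and the mean/median CSMI vectors correlate
strongly on smooth data.

SPGs: seed = `CSMI > 0.15` (strict); with m = min CSMNI over the seed set,
rescue = non-seed genes with `CSMNI ≥ m` (inclusive — the reading that
makes the seed set self-consistent) and `CSPNI > 20`. An empty seed set
calls nothing and warns. The CSMI cutoff is scale-dependent (importance
inherits coordinate units), so it is exposed as a user parameter; on the
dense synthetic panel below, all genes clear 0.15 and the *ranking* is the
informative output.

## Cross-slide validation

Three slides of a patient are rotated through train/val/test combinations
(1,2,3), (2,3,1), (3,1,2). Before transfer, validation and test slides are
rigidly translated so their coordinate centers (mean x, mean y) coincide
with the training slide's center; translation preserves within-slide
distances exactly. The model is retrained on the full training slide with
the hyperparameters chosen by that slide's own cross-validation. Gene sets
are intersected (with counts logged) when per-slide filtering disagrees.

## Synthetic data

The generator emulates one patient: an n × n grid of spots (2-unit
spacing), counts negative-binomial (gamma–Poisson) with
`var = μ + α μ²`, and a lognormal per-spot library factor. Slides of a
patient share one ground truth (surfaces, patch geometry) and differ only
in count noise. Defaults, chosen once:

* dispersion α = 0.5 and mean library ≈ 5,000 counts — Visium-like
  overdispersion at desk scale;
* library-factor lognormal σ = 0.25;
* 6 coordinate-encoding, 6 patch, 48 noise genes on a 15 × 15 grid for the
  benchmark configuration;
* coordinate-encoding surfaces (linear-x, linear-y, radial, x·y product,
  cycling) span a 200× dynamic range. This effect size was calibrated
  against an *independent* oracle (a random-forest regressor), not against
  the network: dispersion 0.5 floors the per-gene log-scale noise at
  ≈ 0.64, and weaker gradients leave spot position undecodable for any
  method. At 200× the oracle localizes spots to ≈ 0.37 of the null MDE,
  i.e. the planted signal genuinely supports coordinate recovery — which is
  the generator's purpose. Near on/off grading of region-restricted genes
  is common in real sections;
* patch genes: 8-fold elevation inside a disc of radius one quarter of the
  slide extent, centered uniformly at random (whole disc inside the slide);
* planted informative genes draw their baseline abundance at 4× the noise
  genes' lognormal baseline, mirroring the observation that genes found
  spatially predictive in real tissue (keratins, mitochondrial and
  ribosomal transcripts) sit far above the median gene in abundance; this
  also keeps the low end of a graded surface above the dropout floor.

What the generator does *not* emulate: histology, cell-type mixtures,
segmentation artifacts, spatial autocorrelation of noise, batch effects
between slides beyond independent count noise, or transcriptome-scale gene
panels. Passing benchmarks on it therefore demonstrates that the pipeline
recovers planted joint-positional signal under realistic count noise — not
performance on any particular tissue.

`evaluate_recovery` scores a run against the truth: median CSMI rank per
class (rank 1 = highest), SPG recall/precision against the planted
coordinate ∪ patch genes (precision flagged undefined when nothing is
called), and the noise fraction among calls.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` use the 15 × 15-grid,
60-gene, 3-slide patient with a single-hidden-layer network at learning
rate 0.01 and k = 10 — 30 model fits, a few seconds end to end. Typical
results (seed 1): per-slide CV-MDE ≈ 4.7–5.0 against a null of 11.46
(ratios 0.41–0.43), planted coordinate genes at median CSMI rank 3.5 of
60, recall 1.0 of planted genes, cross-slide transfer ratios ≈ 0.39–0.40.

## Known limitations

* The 0.15 CSMI threshold is not scale-free; meaningful absolute cutoffs
  require comparable coordinate units and gene-panel sizes. Ranks are the
  robust output on non-standard panels.
* MNI/PNI use a strict zero tolerance; DeepLIFT rarely returns exact zeros
  for connected inputs, so PNI saturates near 100 on dense networks unless
  a tolerance is supplied.
* The multi-output target is attributed as the sum x′ + y′ by default;
  per-axis attributions are provided but the choice is a convention, and
  contributions to x and y can cancel in the summed mode.
* Early stopping with small validation folds (n/k spots) is noisy; the
  fixed val-fold pairing keeps it reproducible but not optimal.
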