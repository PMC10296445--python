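# spglearn

Spatially predictive gene (SPG) discovery for spatial transcriptomics.

Most spatial methods look for *spatially variable genes* (SVGs): genes whose
expression differs significantly across regions of a tissue section. But a
gene does not need to vary sharply in space to carry positional information —
a set of genes can *jointly* encode where a capture spot sits. `spglearn`
finds such **spatially predictive genes** by turning the question around:
train a model to predict each spot's slide coordinates from its expression
profile, then ask which genes the model relied on.

The package is aimed at computational biologists working with Visium-style
data (a spots × genes count matrix plus a spot-coordinate table, one or more
slides per patient/sample).

## Method

**Coordinate regression.** For each slide a dense feedforward network maps a
spot's (filtered, normalized) expression vector to its `(x, y)` coordinates:

    input(n_genes) → [dense → batch-norm → ReLU] × L → dense(2)

Hidden layers follow a halving series whose total width is ≈ half the input
size; weights are He-normal initialized and trained with Adam (batch size 32,
up to 100 epochs, early stopping on validation error). The loss and the
evaluation metric are the same quantity, the **mean distance error**

    MDE = (1/N) Σₙ √((x′ₙ − xₙ)² + (y′ₙ − yₙ)²),

the average Euclidean distance between predicted and true spot positions.
The number of hidden layers (1, 3, 5) and the learning rate (0.1, 0.01,
0.001) are tuned by 10-fold cross-validation in which every fold plays each
role once: 8 folds train, 1 validates (early stopping), 1 tests. The
reference scale for model skill is the *centroid null* — predicting every
spot at the mean coordinate.

**Gene importance.** For every spot, DeepLIFT (Rescale rule, zero reference)
attributes the prediction of the model *for which that spot was in the test
fold* back to the input genes, giving signed contributions `C_gs` that
satisfy completeness (Σ_g C_gs = t − t₀). Importance is the magnitude
`Imp_gs = |C_gs|`, aggregated into:

| statistic | definition |
|---|---|
| MeanImp_g | mean importance over all spots of a slide |
| MNI_g | mean importance over the spots where `Imp_gs > 0` |
| PNI_g | % of spots with `Imp_gs > 0` |
| CSMI / CSMNI / CSPNI | means of the above across a patient's slides |

**SPG call (two stages).** Seed set: genes with `CSMI > 0.15`. Rescue set:
genes whose CSMNI reaches the minimum CSMNI of the seed set and whose
`CSPNI > 20` — genes with strong importance concentrated in a subset of
spots, which slide-wide means underweight. Both thresholds are user
parameters.

A synthetic-data module generates seeded Visium-like patients (grid of
spots, negative-binomial counts) with planted gene classes — coordinate-
encoding, patch-localized and spatially uninformative — so the whole
pipeline can be exercised and benchmarked without any download.

## Worked example

```python
from spglearn import (generate_patient, filter_spots, filter_genes, normalize,
                      variance_filter, cross_validate, centroid_null_mde,
                      build_score_table, select_spgs, evaluate_recovery)
from spglearn.attribution import testfold_importance

slides, truth = generate_patient(n_side=15, n_slides=3, seed=1)
imps = {}
for slide in slides:
    pre = filter_spots(slide, min_genes=slide.n_genes // 2)
    pre = filter_genes(pre)
    pre = normalize(pre)
    pre, _ = variance_filter(pre)
    cv = cross_validate(pre, grid={"n_hidden_layers": (1,), "learning_rate": (0.01,)},
                        k=10, seed=1)
    print(f"{slide.slide_id}: CV-MDE {cv.cv_mde:.2f} "
          f"(centroid null {centroid_null_mde(pre.coords):.2f})")
    imps[slide.slide_id] = testfold_importance(cv, pre)

table = select_spgs(build_score_table(imps))
report = evaluate_recovery(truth, table)
print(f"median CSMI rank by class: {report['median_csmi_rank']}")
print(f"recall of planted coordinate+patch genes: {report['recall']:.2f}")
```

Output:

```
slide1: CV-MDE 4.97 (centroid null 11.46)
slide2: CV-MDE 4.70 (centroid null 11.46)
slide3: CV-MDE 4.86 (centroid null 11.46)
median CSMI rank by class: {'coordinate_encoding': 3.5, 'patch_svg': 15.5, 'noise': 35.5}
recall of planted coordinate+patch genes: 1.00
```

The trained models localize spots to ~4.8 coordinate units (about 2.4 spot
spacings), less than half the centroid-null error of 11.46 — the expression
profiles genuinely encode position. The planted coordinate-encoding genes
occupy the top CSMI ranks (median 3.5 of 60), patch genes rank next, and
spatially uninformative genes fill the lower ranks.

The same workflow is available from the shell:

```sh
spglearn simulate --n-side 15 --n-slides 3 --seed 1 --out sim/
spglearn run --config config.yaml --out results/
```

(`spglearn --help` lists all subcommands: simulate, preprocess, train,
attribute, score, validate, run.)

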