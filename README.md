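# agebrf

Golden-eagle-optimized random-forest analysis of dermoscopic skin-lesion
images: pixel-wise lesion **segmentation** and benign/malignant
**classification**, with the whole pipeline's hyperparameters tuned by a
Golden Eagle Optimization (GEO) metaheuristic.  A synthetic
dermoscopic-image generator with exact ground truth makes every stage
trainable, testable and reproducible without any external dataset.

The intended audience is researchers in medical image analysis who want a
small, fully deterministic, from-scratch reference implementation of a
swarm-tuned classical (non-deep) lesion pipeline.

## Method

**Golden Eagle Optimization.** A population of eagles searches a box-bounded
space; eagle *i* remembers the best point it has visited.  Each iteration it
picks the memory of a random flock member as *prey* and moves by

```
A_i  = x_prey - x_i                          (attack vector)
C_i  ⟂ A_i,  a random point on the hyperplane through x_i     (cruise vector)
Δx_i = r1·pa(t)·A_i + r2·pc(t)·‖A_i‖·Ĉ_i,   r1, r2 ~ U(0,1)
```

with attack/cruise propensities `pa, pc` interpolated linearly over the run
(defaults `pa: 0.5→2.0`, `pc: 1.0→0.5`), shifting the flock from orthogonal
exploration to direct exploitation.  Both step terms scale with the prey
distance, so steps contract as the flock converges.  Minimization, elitist
per-eagle memory, hard clipping to bounds, bit-reproducible per seed.

**Random forest.** CART trees grown on bootstrap resamples; at each node
`ceil(f·F)` candidate features are drawn and the split is the exhaustive
Gini-optimal midpoint of sorted unique values (ties → lowest feature index,
then lowest threshold).  Posteriors are means of leaf class frequencies.
Models serialize to JSON exactly.

**Segmentation.** Each pixel gets a 12-plane feature vector (RGB, HSV,
windowed gray mean/std at 5 and 11 px, gradient magnitude, distance from
center).  A forest trained on stratified pixel samples yields a lesion
posterior map, which is thresholded, cleaned by morphological
opening/closing, and reduced to the largest connected component.

**Classification.** The segmented lesion is summarized by the clinical ABCD
rule — Asymmetry (principal-axis reflection mismatch), Border irregularity
(isoperimetric quotient `P²/4πA`), Color (per-channel mean/std inside the
mask), Diameter (maximum Feret diameter) — and a second forest maps the
10-dimensional descriptor to benign/malignant.

**Joint tuning.** GEO searches the 11 pipeline hyperparameters (both
forests, the posterior threshold and bias, the morphology radius) against
the validation loss `1 − (w_seg·Dice + w_cls·balanced accuracy)`.  One eagle
always starts at the documented defaults, so tuning can never end worse
than the default configuration.

## Worked example

```bash
python examples/segment_and_classify.py
```

trains the default pipeline on 30 synthetic images and evaluates 10
held-out ones:

```
    image_id     dice predicted_label  malignant_posterior true_label
sample_00000 0.973523          benign             0.000000     benign
...
sample_00009 0.991769       malignant             1.000000  malignant

mean Dice          0.979   (overlap between predicted and true lesion masks; 1 = perfect)
balanced accuracy  1.000   (mean of benign and malignant recall)
```

Each row is one held-out image: `dice` measures how well the predicted
mask overlaps the true lesion (1 = pixel-perfect), and the verdict comes
from the ABCD features of the *predicted* mask.  `examples/tune_with_geo.py`
shows the GEO search shrinking the validation loss below the default
configuration's (0.2109 → 0.0471 in a 4-eagle demo), and
`examples/geo_on_benchmarks.py` shows the optimizer reaching ~1e-20 on the
5-D sphere.

The same workflow is available as a CLI:

```bash
agebrf generate --n-benign 50 --n-malignant 50 --out data/
agebrf train    --data data/ --out run/
agebrf tune     --data data/ --out tuned/
agebrf segment  --model run/models.json --image data/images/sample_00000.png --out mask.png
agebrf classify --model run/models.json --image data/images/sample_00000.png --mask mask.png
agebrf evaluate --data data/ --model run/models.json --out eval/
```

Every command derives all randomness from one configured seed and writes a
`run_manifest.json` (config, seed, versions, timings).

## Layout

```
src/agebrf/      library (geo, forest, preprocessing, features, segmentation,
                 classification, pipeline, metrics, synthetic, evaluation, cli)
examples/        runnable narrative scripts, one per capability
tests/           pytest suite (unit, property and acceptance tests)
scripts/         acceptance script
docs/methods.md  modelling assumptions, parameter choices, limitations
```
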