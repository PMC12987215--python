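# craniomorph

Synthetic marker-cap infant head point clouds, constrained semi-synthetic
augmentation, origin-to-marker distance descriptors, and a decision-tree /
random-forest / multilayer-perceptron benchmark for six cranial-shape
classes (brachycephaly, dolichocephaly, normocephaly, plagiocephaly,
towering, trigonocephaly).

## What it does

1. **headgen** — generates marker-labelled head clouds on a parametric
   superellipsoid surface: 135 coded cap markers (4 vertices each, 7 mm
   quads) plus 3 reference stickers (front / left / right preauricular),
   552 vertices for a complete cloud. Per-class geometry (axis lengths,
   posterior shear, anterior taper) keeps the six classes in their
   normative cephalic-index bands. A default 60-cloud cohort
   (10/11/5/9/13/12 per class) reproduces a fixed per-class
   marker-dropout histogram (131–138 present markers).
2. **geometry** — canonical reference frame from the three stickers
   (origin = preauricular midpoint), marker centroids, preauricular
   distance.
3. **augment** — expands each base cloud 60-fold: 20 scale factors
   (stratified random selection from a 0.983–1.016 grid derived from a
   ±1.5 mm preauricular tolerance) × 3 modes (XYZ, XY, Z), plus a rigid
   per-marker uniform perturbation within ±2 mm per axis. 60 bases →
   3600 clouds.
4. **descriptors** — 138-slot vectors of mean origin-to-vertex distances
   in the canonical frame; labelled feature tables (missing slots = NaN).
5. **mlsuite** — train/validation/test splits (60/20/20, 70/15/15,
   90/5/5; stratified; sample- or base-grouped), mean imputation (+
   standardisation for the MLP), hyperparameter searches (DT randomized
   100×3 = 300 fits; RF grid 960×3 = 2880; MLP grid 48×3 = 144),
   high/low-performance tier configurations, and macro
   precision/recall/F1 + confusion + timing reports.
6. **io / cli** — cloud CSV (one row per vertex), binary PLY export,
   feature CSV, YAML configs, seeded end-to-end pipeline.

## CLI

```bash
craniomorph generate --out run/ --seed 7              # 60 base clouds
craniomorph augment  --in run/bases.csv --out run/ --seed 7
craniomorph features --in run/augmented.csv --out run/features.csv
craniomorph train    --features run/features.csv --out run/results/ --seeds 0,1,2
craniomorph report   --in run/results/
craniomorph pipeline --config config.yaml             # all stages, one seed
craniomorph fixtures --out fixtures/                  # toy example clouds
```

Minimal `config.yaml`:

```yaml
seed: 7
out_dir: run
eval_seeds: [0, 1, 2]
group_level: sample   # or "base" for leakage-free grouped splits
```

## Layout

```
src/craniomorph/
  cloud.py        # HeadCloud data model, slots/roles/label codes
  headgen.py      # ShapeParams, CohortPlan, generators, cephalic index
  geometry.py     # ReferenceFrame, centroids, preauricular distance
  augment.py      # ScalePlan, ScaleMode, NoiseSpec, augmentation ops
  descriptors.py  # DescriptorVector, feature tables
  mlsuite.py      # splits, preprocessing, searches, tiers, evaluation
  io.py           # CSV/PLY/YAML/JSON, pipeline runner, seed derivation
  cli.py          # click command group
```
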