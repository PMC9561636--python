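# phenoscreen

Image-based phenotypic profiling and screening statistics for multi-well
neuronal assays: synthetic plate and field-image generation with ground
truth, segmentation and well-level feature extraction against declared
feature catalogues, plate-wise preprocessing, two-class reference-model
classification with decision-space mapping, and screening statistics
(Z-factor, leave-one-feature-out attribution, 3-SD hit calling,
replicate-power analysis).

## Modules

| module        | role |
|---------------|------|
| `catalogue`   | declared feature catalogues per staining panel (four-channel panel: 126 features, 54 on the TH+ subpopulation; mitochondrial panel: 96; LAMP1 panel) |
| `synthgen`    | 384-well layouts (edge wells excluded, 9 fields/well), effect profiles (mutant phenotype, compound rescue shifts), noise model, feature-table sampling and field-image rendering with exact ground truth |
| `imfeat`      | illumination correction, per-plate auto thresholds, rolling-ball + top-hat mitochondria segmentation, neurite skeletonization, marker-positive cell calling, per-well feature computation |
| `prep`        | per-plate median normalization to a reference condition, robust outlier-well removal, greedy Pearson decorrelation; replayable `PrepReport` |
| `profclass`   | LDA / linear-SVM / gradient-boosting reference models (25× stratified 80/20 shuffle splits with grid search), normalized well scores (class medians anchored at 0 and 1), cross-plate validation, PCA embedding |
| `screenstats` | Z-factor, LOOCV feature attribution, k-SD hit calling, replicate-power (Monte-Carlo and analytic), Mann-Whitney / Welch tests, bootstrap median CIs |
| `cli`         | `phenoscreen` command with `simulate-plate`, `extract-features`, `preprocess`, `train`, `classify`, `zfactor`, `loocv`, `hits`, `power`, `embed`, `run` |

## Quick start

```bash
# synthesize a plate (plate map + well-level feature table)
phenoscreen simulate-plate --panel A --seed 1 --out plate1/

# full synthetic pipeline from a YAML config
printf 'out_dir: run1\nseed: 1\nn_plates: 2\n' > cfg.yaml
phenoscreen run cfg.yaml

# replicate-power: wells needed to detect one >3-SD hit at effect size 2
phenoscreen power --d 2 --target 0.85 --method analytic
```

Python API:

```python
from phenoscreen import get_catalogue
from phenoscreen.synthgen import PlateSpec, make_layout, sample_feature_table, \
    DEFAULT_PROFILES, NoiseModel
from phenoscreen.prep import preprocess
from phenoscreen.profclass import train_reference, score_wells

cat = get_catalogue("panelA")
layout = make_layout(PlateSpec(), [("control", "fill"), ("mutant", "fill")], seed=0)
table, truth = sample_feature_table(layout, cat, DEFAULT_PROFILES, NoiseModel(), seed=0)
proc, report = preprocess(table, "control")
model = train_reference(proc, "control", "mutant", "SVM")
scores = score_wells(model, proc)       # control median -> 0, mutant median -> 1
```

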