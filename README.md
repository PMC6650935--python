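# sppe — spatial pyramid partition ensemble for flour-image classification

`sppe` classifies granular-material images (e.g. barley flour, malting vs
naked) with a weighted sub-region voting ensemble:

1. **ROI extraction** — Otsu thresholding of the intensity channel, hole
   filling, center of mass, and growth of the largest all-foreground square.
2. **Spatial pyramid partition** — the ROI (level 0) is quartered into 4
   level-1 tiles, each quartered again into 16 level-2 tiles: 21 regions.
3. **Feature extraction** — every region is described by 55 features:
   30 color (HSV + CIE L\*a\*b\* moments and histogram statistics),
   6 intensity, 10 rotation-invariant uniform LBP, 5 GLCM (d=1, 0°, 256 grey
   levels) and 4 FFT spectral statistics.
4. **Weighted voting** — one classifier is trained on all level-1/2
   sub-region rows; a sample's label is the weighted majority vote of its 20
   sub-region predictions (level-1 members weigh 1/3, level-2 members 1/12,
   so each level carries equal influence). Ties fall back to the level-0
   prediction.

Two baselines are included: the **traditional** whole-ROI 55-feature
descriptor and the concatenated **spp** 1155-feature vector (21 × 55).
Evaluation is always group-bound — all regions of a sample stay together
(leave-one-sample-out or grouped k-fold), enforced by a hard assertion.

A fully seeded synthetic generator (`sppe.synthetic`) emulates the two-class
flour dataset design (14 + 8 cultivars × 5 images = 110 samples, 70/40)
with class-dependent color means, per-cultivar offsets, granular noise and
dark elongated "husk" speckles, so the whole pipeline is testable without
the original images.

## CLI

```sh
sppe simulate --seed 1 --out data/                    # images + manifest.csv
sppe extract  --manifest data/manifest.csv --mode sppe --out regions.csv
sppe train    --features regions.csv --classifier tree --out model.sppe
sppe predict  --features regions.csv --model model.sppe --out preds.csv
sppe evaluate --features regions.csv --scheme loso --out report.json
sppe compare  --features regions.csv --scheme kennard-stone --out grid.csv
```

`extract --mode sppe` writes the full region table (one row per region, 21
per sample); `--mode traditional` / `--mode spp` write one row per sample
(width 55 / 1155). `evaluate` supports `loso`, grouped `kfold`, and a
deterministic `kennard-stone` 90/20 sample split. `compare` runs all
4 classifiers (rf, knn, tree, svm) × 3 methods and tabulates accuracy,
precision and recall. Exit codes: 0 ok, 2 config error, 3 data error.

## Conventions worth knowing

* Intensity = mean(R, G, B); H, S, V in [0, 1]; L\* in [0, 100]; a\*, b\*
  native signed scale (sRGB, D65).
* "Histogram" features are moments of the 256-bin count sequence of a
  channel histogram, distinct from the pixel-level mean/std features.
* All entropies are in bits; kurtosis is excess kurtosis.
* The four FFT statistics treat the DC-excluded normalized power spectrum
  as a distribution with the radial frequency distance in the role GLCM
  gives to |i − j|; a constant region defines all four as 0. These
  definitions are this package's documented completion — the feature names
  fix only the statistic, not the formula.
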