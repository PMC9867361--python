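# cervitex

Quantitative prediction of neck-pain status from lateral cervical-spine
radiographs, for researchers studying musculoskeletal effects of
prolonged hand-held device use.

Heavy daily social-media use on hand-held screens is associated with
sustained neck flexion and, eventually, perceived neck pain.  `cervitex`
implements a full quantitative pipeline for studying that association on
lateral neck X-rays:

* **Image enhancement** — a nine-step chain (window adjustment, ROI
  crop, repeated 3×3 mean smoothing, unsharp sharpening, Sobel edge
  detection, an FFT band-pass that removes structures larger than 40 px
  and smaller than 3 px with optional scan-line stripe suppression, and
  standardisation to a 256×256 8-bit raster).
* **Texture features** — the normalised gray-level co-occurrence matrix
  P(i,j) and four scalars: contrast Σ P(i,j)(i−j)², homogeneity
  Σ P(i,j)/(1+(i−j)²), correlation Σ P(i,j)(i−μᵢ)(j−μⱼ)/√(σᵢ²σⱼ²), and
  energy √(Σ P(i,j)²) — the square root of the angular second moment.
* **Curve geometry** — a smooth curve through the ordered C1…C7
  vertebral landmarks gives `angle_1` (tangent at C7 vs the horizontal),
  `angle_2` (tangent at C1), and the area enclosed between the curve and
  the C1–C7 chord.
* **Three classifiers** — (i) a published IF-THEN rule set over usage
  category, age, contrast and angle_1; (ii) a deployed symbolic scoring
  model H = 1/(1 + e^(t₁·y + t₂)) with t₁ = −1797.29, t₂ = 7.28, where
  H ≥ 0.5 means no perceived pain; and (iii) a from-scratch
  cost-sensitive C4.5-style decision-tree trainer (information-gain
  splits, instance reweighting by a misclassification cost matrix,
  default [(0,1),(5,0)] over (abnormal, normal)).
* **Evaluation** — confusion matrices with a declared positive class,
  per-class and support-weighted precision/recall/F1, stratified k-fold
  cross-validation, descriptive statistics and box-plot summaries per
  usage band.

The package bundles the 46-patient study cohort (19 male / 27 female;
8 pain-free, 38 with perceived pain) as a plain CSV, and ships a
synthetic-phantom generator — a curved chain of vertebra-like blobs with
analytically known end angles and chord area — so every image-facing
stage is testable without clinical data.

## Worked example

```python
>>> import cervitex as cx
>>> records = cx.load_cohort()                      # bundled 46-patient cohort
>>> cx.reproduction_block()
{'TP': 8, 'TN': 34, 'FP': 4, 'FN': 0, 'accuracy_pct': 91.3}
```

Thresholding the bundled per-patient sigmoid scores at 0.5 (pain-free
class positive) classifies all 8 pain-free subjects correctly, 34 of the
38 painful subjects correctly, and mislabels 4 painful subjects as
pain-free: accuracy 42/46 = 91.30 %.

```python
>>> res = cx.CervicalPainTree(records).fit(train_fraction=2/3, seed=0)
>>> print(res.summary())
Cost-sensitive decision tree (C4.5-style, information gain, unpruned)
  features: gender, age, h_mean, angle_1, angle_2, area, contrast, ...
  cost matrix: ((0.0, 1.0), (5.0, 0.0)) over classes (0, 1)
  ...
```

The five-fold cost on the minority pain-free class makes the tree
reluctant to call a pain-free subject painful; on the full cohort this
raises pain-free recall from 0.875 (unit costs) to 1.0.

A phantom run from the shell:

```sh
$ cervitex simulate ph.png --landmarks-out marks.json --angle1 80 --angle2 55 --seed 1
$ cervitex preprocess ph.png pp.png
$ cervitex features pp.png --landmarks marks.json
{
  "contrast": 0.741, "homogeneity": 0.717, "correlation": 0.642,
  "energy": 0.327, "angle_1": 80.54, "angle_2": 54.30, ...
}
```

The recovered end angles sit within ~0.6° of the generating values, and
the texture features fall inside the cohort's observed ranges.

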