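# dualifc

Analysis pipeline for **dual-modality 3D imaging flow cytometry** of single
cells. A 3D imaging flow cytometer records, for every cell passing the
interrogation region, a 2D transmission image (80×80 px, 40×40 µm field of
view) and a 3D side-scatter stack (40×40×40 voxels, 40 µm per axis),
reconstructed from temporal detector signals by a fixed temporal–spatial
mapping. Applied to liver cells — hepatic stellate cells (HSC) and liver
endothelial cells (LEC) from healthy donors and NASH patients — such image
pairs carry label-free morphological and textural signatures of disease.

This package provides, on fully synthetic data:

- a **phantom generator**: ellipsoidal cells with Gaussian-random-field
  internal texture, vacuoles, and class-conditional effect sizes
  (diseased = finer texture → higher co-occurrence entropy, lower
  homogeneity/energy; slightly larger volume; more vacuolation), rendered
  into transmission (Beer–Lambert projection) and side-scatter stacks;
- an idealized **scan simulator**: the bijective temporal encoding /
  decoding of the optical-sectioning readout;
- **preprocessing**: intensity-threshold background removal, global
  per-modality normalization, per-subject class-balanced sampling
  (5000 pairs/subject → 20,000 per 2+2-subject cohort);
- a fixed **55-feature panel** per cell — 28 from the 2D image and 27 from
  the 3D stack: geometric morphometry (area, perimeter, volume, surface
  area, elliptical-fit axes, sphericity, …), first-order intensity
  statistics, and 13 Haralick texture statistics averaged over 16 (2D:
  d ∈ {1,2,3,4} × θ ∈ {0°,45°,90°,135°}) and 52 (3D: 13 unique
  26-neighborhood directions × 4 offsets) gray-level co-occurrence
  matrices, with z-score normalization r_n = (r − mean)/σ;
- a **benchmark of seven conventional classifiers** (logistic regression,
  k-NN, RBF SVC, random forest, gradient boosting, naive Bayes, Gaussian
  process) under subject-stratified 4-fold cross-validation, reporting
  per-fold confusion matrices, macro precision/recall/F1 and balanced
  accuracy (mean of per-class recall);
- a **fused 2D+3D UNet autoencoder-classifier** written in numpy with
  explicit backpropagation: two UNet branches reconstruct their input
  modality while their pooled bottlenecks are concatenated into a softmax
  classifier, trained with the weighted loss
  L = w₂·L_CE + (1−w₂)·(w₁·MSE_2d + (1−w₁)·MSE_3d)
  under Adam (β₁ = 0.99, β₂ = 0.9999 by default), a warm-up learning-rate
  schedule (1e-5 for five epochs, then 5e-5) and plateau halving.

## Worked example

```python
import numpy as np
from dualifc import CohortDesign, PRESETS, generate_cohort, extract_table
from dualifc.preprocess import remove_background_dataset, normalize_global
from dualifc.features import FeatureTable
from dualifc.bench import benchmark, stratified_folds

design = CohortDesign(cells_per_subject=50,
                      class_params_map=dict(PRESETS["default"]), seed=0)
cohort = normalize_global(remove_background_dataset(generate_cohort(design)))
table = FeatureTable(frame=extract_table(cohort, transmission_is_absorbance=True))

means = table.frame.groupby("label")[["volume_3d", "entropy_3d", "homogeneity_3d"]].mean()
print(means.round(3))

folds = stratified_folds(table.labels, k=4, seed=0,
                         subjects=table.frame["subject_id"].to_numpy())
results = benchmark(table, folds, seed=0)
for name, r in results.items():
    print(f"{name:22s} mean F1 {r.mean_f1:.3f}")
```

prints (200 cells, default presets):

```
          volume_3d  entropy_3d  homogeneity_3d
label
diseased    2307.85       9.404           0.212
healthy     2094.03       8.632           0.290
logistic_regression    mean F1 1.000
k_nearest_neighbors    mean F1 0.990
svc_rbf                mean F1 1.000
random_forest          mean F1 1.000
gradient_boosting      mean F1 1.000
naive_bayes            mean F1 0.995
gaussian_process       mean F1 0.995
```

— the diseased class shows the configured ~10 % volume increase
(2308/2094 ≈ 1.10 in µm³) and the higher-entropy / lower-homogeneity
texture, and every model separates this clearly contrasted small cohort
almost perfectly. Training the fused model on the raw image pairs instead
uses `dualifc.nn.cross_validate`; the CLI (`dualifc simulate / preprocess /
extract / bench / cv-unet / run`) chains the same stages from the shell.

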