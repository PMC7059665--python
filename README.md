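# hsistress

Ground-based visible/near-infrared (VNIR, 380–1030 nm) hyperspectral
imaging can separate rice seedlings that are healthy (CK), stressed by the
auxin-mimic herbicide quinclorac (Q), or rescued by a salicylic-acid
pretreatment before the herbicide (S): pigment loss raises visible
reflectance (434–700 nm) while structural damage lowers the NIR plateau
(750–953 nm), with the rescued group sitting between the control and the
stressed group but much closer to the stressed one. `hsistress`
implements the full analysis chain for this three-way phenotyping problem
as a tested, reusable Python package, for plant-phenotyping and
chemometrics researchers who want to run, audit or extend the workflow.

The chain, for hyperspectral cubes `I_raw` with dark/white reference
frames `B`, `W`:

1. **Reflectance calibration** — `R = (I_raw − B) / (W − B)`, ENVI-style
   cube I/O (`bil`/`bip`/`bsq`).
2. **Segmentation and preprocessing** — vegetation mask from the
   normalized difference `(R800 − R680)/(R800 + R680)`; per-pixel spectra
   cropped to the 410 bands covering 434–953 nm, denoised by keeping the
   level-3 Daubechies-9 wavelet approximation, then smoothed with a
   7-point moving average; per-sample mean spectrum.
3. **Chemometrics** — centering-only PCA (`SpectralPCA`) for score images
   and 10-component feature extraction; Kennard–Stone sample ranking used
   either for a 2:1 calibration/prediction split or a per-class 4:1:1
   train/validation/test split.
4. **Classification** — soft-margin support vector classification with
   the RBF kernel `K(u,v) = exp(−γ‖u−v‖²)`, written from scratch: the
   dual `min ½αᵀQα − eᵀα` s.t. `yᵀα = 0`, `0 ≤ αᵢ ≤ C` is solved by
   maximal-violating-pair SMO; multiclass via one-vs-one voting
   (`RBFSupportVectorClassifier`, a scikit-learn-style estimator);
   `(C, γ)` tuned on a 17×17 log-decade grid (`10^N`, `N = −8..8`)
   scored on the validation set.
5. **Evaluation and mapping** — 3×3 confusion matrices, accuracy,
   unweighted Cohen's kappa `κ = (p_o − p_e)/(1 − p_e)`, and pixel-wise
   prediction maps with per-category pixel fractions.

Because the original study's images were never deposited, the package
ships a first-class synthetic-scene generator (`hsistress.synthetic`)
that reproduces the reported spectral contrasts — leaf-shaped regions
with pigment absorptions, red edge and NIR plateau, treatment-dependent
visible/NIR offsets, pixel-level scatter and noise, inverted through the
calibration equation into raw counts — so every stage runs end to end.

## Worked example

```sh
hsistress all --seed 1 --outdir run
```

runs simulate → calibrate → preprocess → split → train → evaluate → map
on the default synthetic study (40 scenes per group) and prints:

```
 feature_mode     subset  n  accuracy  kappa  ...
full_spectrum      train 84       1.0    1.0  ...
full_spectrum validation 18       1.0    1.0  ...
full_spectrum       test 18       1.0    1.0  ...
         pc10      train 84       1.0    1.0  ...
         pc10 validation 18       1.0    1.0  ...
         pc10       test 18       1.0    1.0  ...
majority pixel category matches truth for 100.0% of scenes
artifacts in run
```

Both the 410-band and the 10-PC-score models classify every sample of
every subset correctly under the default effect sizes and noise — the
synthetic contrasts are deliberately clean enough for this — and in every
scene's pixel-wise map the majority predicted category is the scene's
true treatment.  `run/` contains the manifest, preprocessed spectra,
split assignment, grid-search tables, serialized PCA/SVC models, the
metrics table, per-scene predicted-pixel fractions and rendered maps.

The same from Python:

```python
from hsistress import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=1, outdir="run"))
print(report.metrics)                 # accuracy/kappa per mode and subset
print(report.majority_match_fraction) # 1.0
```

`hsistress evaluate` prints accuracy and Cohen's kappa recomputed from
the benchmark confusion matrices of the original two-cultivar study
(e.g. Xiushui 134 full-spectrum training: accuracy 93.67%, κ 90.49%).

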