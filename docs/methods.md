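# Methods

## Problem and model

Three treatment groups of rice seedlings are to be told apart from
ground-based VNIR hyperspectral images: untreated controls (CK, label 1),
seedlings stressed with the herbicide quinclorac (Q, label 2), and
seedlings given a salicylic-acid pretreatment before the herbicide
(S, label 3).  The physiological signature is spectral: herbicide damage
reduces leaf pigments (raising reflectance in the 434–700 nm pigment
window) and degrades cell structure (lowering reflectance on the
750–953 nm NIR plateau); the rescue treatment moves both effects part of
the way back toward the control.  Classification is done on per-sample
mean reflectance spectra, either on all 410 retained bands or on ten PCA
scores, with a one-vs-one soft-margin RBF support vector classifier.

## Reflectance calibration and ENVI I/O

Raw counts become reflectance via `R = (I_raw − B)/(W − B)` with dark and
white reference lines broadcast down the scan axis (line-scan geometry).
Elements with `|W − B| < 1e-12` are set to 0 and counted in a calibration
report; above 1% such elements a warning is raised (an error in strict
mode), since a dead reference usually means a failed acquisition.  Cubes
are stored in a minimal ENVI dialect — ASCII header with an `ENVI` magic
line, lowercase keys, braced wavelength list in nm; float32 for
reflectance, uint16 for raw counts; `bil`/`bip`/`bsq` interleaves — which
is a deliberate smallest interoperable subset, not a full ENVI reader.

## Preprocessing chain

The order is fixed and mirrors the acquisition workflow: segment →
extract pixel spectra → crop to 434–953 nm → wavelet denoise → moving
average → per-sample mean.

* **Segmentation**: normalized difference `(R800 − R680)/(R800 + R680)
  > 0.4`, connected components below 20 px removed.  A
  vegetation-index rule replaces the manual commercial-software
  segmentation of the original workflow, which is not reproducible.
* **Band window**: the retained window runs from the last band at or
  below 434 nm through the first band at or above 953 nm, so the
  requested range is fully covered; on the 512-band 380–1030 nm axis
  this yields exactly 410 bands.  (A strict `lo ≤ λ ≤ hi` filter would
  give 408 and is incompatible with the 410-band feature count the
  downstream stages assume.)
* **Denoising**: 3-level Daubechies-9 decomposition with symmetric
  boundary extension; all detail coefficients zeroed; reconstruction
  truncated to the input length.  Zeroing details is the only
  parameter-free reading of "wavelet transform at level 3" — no
  threshold rule is introduced.  With symmetric extension the operator
  is an exact projection away from the ends (idempotence deviation
  < 1e-14 beyond 100 bands from either end) but not at them; boundary
  deviations stay ~1e-4 relative.
* **Smoothing**: centered 7-point moving average whose window shrinks
  symmetrically at the ends (unbiased for locally symmetric signals,
  no padding artifacts at the 434/953 nm edges).
* Per-pixel preprocessing precedes averaging even though mean-then-smooth
  would be cheaper, because the pixel-wise spectra are also what the
  prediction maps classify.

## Synthetic scenes

The generator emulates the study conditions: 512 uniform bands over
380–1030 nm; a deterministic healthy-leaf curve (visible baseline 0.08,
sigmoid red edge centered 715 nm of width 18 nm rising to an NIR plateau
of 0.50, green bump at 550 nm of height 0.07, multiplicative pigment
absorption dips at 450 nm/depth 0.42/sd 40 nm and 680 nm/depth 0.40/sd
25 nm); additive treatment offsets of +0.04/+0.03 (Q/S) on 434–700 nm and
−0.05/−0.04 on 750–953 nm.  The offsets are free parameters chosen so the
classes are separable but Q and S remain mutually closest — the
qualitative error structure of the original experiment; no quantitative
reflectance deltas were ever published, so these are design choices, not
reproduced facts.

Offset transitions are half-cosine ramps spanning 30 nm placed just
inside each window edge (`taper_nm = 15` is the ramp half-width).  Ramps
of exactly 15 nm total span would be attenuated by the fixed smoothers by
~3.5e-3 reflectance at the transition, defeating the noiseless recovery
check below; the 30 nm inside-placed ramps have zero slope at the window
edges (which for the visible window coincide with the crop boundary) and
keep the mean visible offset within 0.005 of the nominal +0.04.

Scenes are 64×64 px with 3 non-overlapping elongated ellipses (semi-axes
~3–4.5 × 14–20 px) on a flat background of reflectance 0.03 — a scaled
stand-in for the original 672-px-wide line scans, chosen so the default
120-scene study runs in minutes on one core.  Pixel-level realism:
multiplicative slope scatter (sd 0.05), additive offset scatter
(sd 0.01), band-wise Gaussian noise (sd 0.01).  The reflectance scene is
inverted through the calibration equation with synthetic references
(dark ≈ 100 counts; white ≈ 3000 counts with a halogen-like spectral
shape) plus count-domain noise (sd `0.3·sqrt(counts)`) and small
reference noise (sd 2 counts), so calibration sits on the main path.
Everything is a pure function of (params, seed).

What the generator does **not** model: radiative transfer
(PROSPECT/SAIL-class realism), specular/shadow effects, leaf venation or
within-leaf gradients, temporal stress dynamics, cultivar differences.
Passing tests therefore demonstrate the correctness and stability of the
pipeline's computations, not field-level classification performance.

## PCA

Centering-only (no variance scaling — reflectance bands share units),
via SVD; component signs fixed so each loading's largest-magnitude
element is positive, making score images reproducible run to run.
`explained_variance_ratio_` is `σ_j²/Σσ²`.  For classification features
the PCA is fitted on training samples only; ten components are used.
Under default noise, ten centered components carry ≈98.7% of pooled
preprocessed pixel variance (the remainder is the per-band noise floor);
the uncentered ten-component fraction — what score-image software
commonly reports — exceeds 99.99%.

## Dataset splitting

Kennard–Stone ranks samples by iteratively maximizing the minimum
Euclidean distance to the already-selected set, seeded by the farthest
pair; ties break toward the lowest index so the ranking is deterministic.
Two split modes exist: a 2:1 calibration/prediction split, and the
pipeline default 4:1:1 in which each class's Kennard–Stone ranking is
dealt round-robin as train, train, train, train, validation, test — so
all three subsets sample each class's spectral extremes and per-class
validation/test counts stay within one of `⌊n_c/6⌋`.

## Support vector classification

The binary dual (RBF kernel, penalty C) is solved by two-variable
working-set ascent with maximal-violating-pair selection, stopping when
the KKT violation `m(α) − M(α) ≤ tol` (default 1e-3; iteration cap
`10⁴·n`).  The bias is the mean of `y_i − Σ_j α_j y_j K(x_j, x_i)` over
free support vectors, or the midpoint of the feasible interval when none
is free.  Multiclass = one-vs-one with majority voting; vote ties break
toward the tied label with the largest summed |decision value| over the
machines it won, then toward the smallest label value.  Features enter
unscaled (reflectance is already in [0, 1]; PC scores as produced).

Grid search trains one model per `(C, γ)` cell on the training set and
selects by validation accuracy, ties broken by training accuracy, then
smaller C, then smaller γ — when many cells are perfect this
deliberately prefers the least complex machine.  The default grid is
`{10^N : N = −8..8}²` (289 cells).

Verification is dual-route: on random small problems the SMO dual
objective is compared against multipliers obtained from libsvm (an
independent implementation, agreement ≤ 3e-9) and against a generic
SLSQP quadratic-programming solve where that solver converges; on the
analytic two-point problem `α = 1/(1 − e⁻¹)`, `b = 0` is recovered to
1e-6.

## Evaluation and maps

Accuracy is trace/total of the 3×3 confusion matrix; kappa is unweighted
Cohen's kappa (undefined and refused when all mass sits in one cell).
Pixel maps push every plant pixel through the same crop/denoise/smooth
chain, project onto the fitted components and classify with the 10-PC
model; background pixels carry label 0, and per-category pixel fractions
summarize each scene (Q↔S confusion dominates the off-diagonal mass, as
in the original report).

The benchmark confusion matrices of the original two-cultivar experiment
are bundled (`hsistress.reference`); all twelve reported accuracies
reproduce exactly, as do the reported kappas 84.96/92.51/92.5/100.  Two
reported training kappas (90.47, 86.68) differ from the exact values of
their own matrices (90.49, 86.67) by ≤0.02 — rounding in the original
report — and three further reported kappas (80.65, 76.15, 80.5) are not
consistent with any common kappa variant computed from their matrices
and are excluded from comparisons.

## Numerical choices and defaults

| Parameter | Default | Why |
| --- | --- | --- |
| band window | 434–953 nm (410 bands) | stated analysis range |
| wavelet, level | db9, 3 | stated denoiser |
| smoothing window | 7 points | stated smoother |
| PCA components | 10 | stated feature count |
| split | 4:1:1 per class | stated design (2:1 Kennard–Stone also available) |
| grid | `10^N`, N = −8..8 | stated tuning range |
| SMO tol / cap | 1e-3 / 10⁴·n | exact on small problems, bounded runtime |
| segmentation threshold | 0.4, min 20 px | separates leaf (index ≳ 0.6) from background (≈0) with wide margin |
| scenes per group | 40 | large enough for a 28/6/6 per-class split, minutes of runtime |

Degenerate inputs are refused loudly rather than patched: empty masks,
single-class training sets, zero-variance PCA input, duplicate-only
Kennard–Stone input, kappa with `p_e = 1`.

## Known limitations

* The original study's cultivar-specific chosen `(C, γ)` values and its
  real-data accuracies cannot be reproduced without the undeposited
  images; the synthetic study is a scaled stand-in whose perfect
  accuracies reflect the chosen effect sizes, not field difficulty.
* The noiseless-recovery bound (RMS < 1e-3 per band across the chain) is
  a property of the generator's smooth spectra; sharper real-world
  features would be attenuated more by the fixed smoothers.
* One-vs-one voting and the grid-search tie rule are design choices; the
  original report does not state its multiclass scheme or tie handling.
* The wavelet stage assumes ≥136 bands (level-3 db9 support); shorter
  spectra are refused.
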