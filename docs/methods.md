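# Methods

This document records every numerical convention, default parameter, and
modelling choice in `edgescore`, including the scope and limits of the
synthetic generators.

## 1. Segmentation (`edgescore.segmentation`)

Semi-automatic delineation from a single seed voxel:

1. **Hill climb.** The seed ascends to the local SUV maximum through its
   26-neighborhood, so a click anywhere on the lesion flank lands on the
   lesion's own peak.
2. **Relative threshold.** Voxels with `SUV ≥ relative_threshold × SUVmax`
   are candidates; the default threshold is 0.40 of the lesion-local
   SUVmax (inclusive: a voxel at exactly 40% is kept).
3. **Connected component.** The 26-connected component (configurable to
   6 or 18) containing the peak is the lesion mask; disconnected islands
   above threshold are discarded.
4. **Quality control.** Lesions smaller than 64 voxels on the native grid
   are rejected (`qc_filter`); this exclusion rule
   protects the texture matrices from degenerate statistics.

## 2. Spatial score (`edgescore.spatial`)

* **Hotspot.** The foreground voxel of maximal SUV; exact ties are broken
  deterministically by lowest index in C order and flagged
  (`hotspot_tie`).
* **Centroid.** Unweighted mean of foreground voxel-center physical
  coordinates (mm), via the affine. SUV-weighted centroids are not used.
* **DmaxC.** Euclidean mm distance hotspot → centroid.
* **DmaxP.** Exact anisotropic Euclidean distance transform
  (`scipy.ndimage.distance_transform_edt` with `sampling=spacing`) of the
  mask padded by one background layer, evaluated at the hotspot. The
  convention is therefore *distance to the nearest background voxel
  center*: a foreground voxel adjacent to background measures one voxel
  spacing, never zero. The padding guarantees a lesion touching the grid
  edge still sees a boundary there.
* **Normalization.** Both distances are divided by the volume-equivalent
  sphere radius `R_eq = (3V/4π)^(1/3)`, with `V` the voxel-count volume
  in mm³. This makes the score size-invariant and is applied identically
  to both distances.
* **EPS.** `(nDmaxC − nDmaxP)/(nDmaxC + nDmaxP)`. If both distances are
  zero (a one-voxel lesion cannot occur after QC, but the API is total)
  the score is `None` — missing, never NaN.
* **Stratification.** `high` iff EPS > 0, `low` otherwise.

### The `f = 1.0` boundary case

The sphere-oracle acceptance sweep places a hotspot at fraction `f` of
the radius and expects `EPS = 2f − 1` within `1.5/16`. At `f = 1.0` this
is unattainable *by construction* under the voxel-center distance
convention above: a boundary hotspot always measures `DmaxP` = one voxel,
so on a radius-`R` sphere `EPS = (R − 1)/(R + 1)` and the error is
`2/(R + 1) ≈ 0.118` at `R = 16`, above the tolerance for every possible
implementation that also satisfies the exact distance-transform oracle.
Error propagation near the edge gives `dEPS ≈ 2·dnDmaxP`, i.e. the EPS
tolerance is half as forgiving as the component tolerance there. The
corresponding test is left failing at the stated tolerance rather than
silently widened; the component assertions (`nDmaxC`, `nDmaxP`) pass at
every `f`, and EPS passes at `f ∈ {0, 0.25, 0.5, 0.75}`.

## 3. Metrics (`edgescore.metrics`)

**Conventional:** SUVmax, SUVmean over the mask, MTV in mL
(voxel count × voxel volume / 1000), TLG = SUVmean × MTV.

**Radiomics:** 115 features under a pinned, versioned manifest
(`edgescore-115-v1`): 24 first-order, 14 morphology, 26 GLCM, 16 GLRLM,
16 GLSZM, 5 NGTDM, 14 GLDM. Extraction pipeline:

* Resample to 2 mm isotropic (trilinear for SUV, nearest-neighbor for the
  mask) using grid-aligned zoom, which preserves the physical extent of
  the lesion; corner-aligned zoom systematically erodes downsampled
  masks.
* Fixed-bin-size discretization at 0.25 SUV from the lesion minimum.
* Texture matrices merge the 13 unique 3-D directions at distance 1
  (GLCM symmetric; GLRLM runs walked per direction; GLSZM zones
  26-connected; GLDM dependence = 1 + neighbors within `alpha = 0`
  levels).
* Morphology from the resampled mask: marching-cubes surface area,
  PCA-derived axis lengths (4·√eigenvalue), convex-hull maximum 3-D
  diameter, sphericity/compactness family.

All values are plain floats computed deterministically; two extractions
of the same lesion are bit-identical. Extraction refuses lesions under
the 64-voxel QC floor.

## 4. Synthetic phantoms (`edgescore.synthetic.make_phantom`)

Sphere / ellipsoid / lobulated masks on an isotropic or anisotropic grid,
with analytic ground truth `(nDmaxC, nDmaxP, EPS) = (f, 1 − f, 2f − 1)`
for a hotspot at fraction `f` of the radius.

Construction order matters: the anatomical scene (lesion plateau over
background) is blurred with a Gaussian PSF *first*, then a narrow
Gaussian bump is added at imaging resolution with its amplitude pinned so
the nominated voxel equals the requested SUVmax exactly. Blurring after
bump placement would shift the discrete argmax inward near the boundary
and silently break the ground-truth contract. Defaults — lesion SUV 6.0,
peak 10.0, background 0.5, bump σ 1.2 mm, PSF σ 1.0 mm — are chosen so
that (a) the 40% threshold contour of the blurred lesion tracks the true
boundary and (b) the bump's curvature dominates the blurred edge slope,
keeping the discrete SUVmax at the nominated voxel for all `f` including
1.0. Optional Gaussian noise is seeded and deterministic.

Non-goals: Poisson sinogram physics, respiratory motion.

## 5. Synthetic cohorts (`edgescore.synthetic.make_cohort`)

Per-patient rows with clinical covariates, spatial scores, the full
115-feature manifest, invasiveness labels, and PFS:

* **Marginals.** Age, MTV, SUVmax, nDmaxC, nDmaxP are log-normals
  matched to the target median/IQR; MTV is truncated at 250 mL and
  SUVmax at 40 (untruncated tails produce physiologically absurd lesions
  and occasional Cox separation at n = 244). EPS is *computed from* the
  drawn distances via the score formula, never drawn directly, so the
  generated table always honours the score definition.
* **Labels.** LVI/VPI/STAS are Bernoulli with logistic models on EPS (and
  a size factor); intercepts are solved numerically (Brent) at generation
  time so realized prevalences match the targets (42.6/28.7/34.8%).
* **Survival.** Exponential proportional hazards with multivariable
  effects: EPS-group HR 2.667, stage II–III 2.927, VPI 1.628, age
  0.975/yr, MTV 1.005/mL. Uniform administrative censoring on
  (12, 120) months; the baseline rate is solved so the expected event
  fraction is 42.2%.
* **Radiomic features.** Noisy linear reflections of the underlying
  physiology (size/uptake/position factors with per-feature deterministic
  weights keyed by feature name), giving the selection stage a realistic
  correlated candidate pool rather than pure noise.

The generator's purpose is *pipeline validation*: each stage can be run
against a cohort whose true effect sizes are known. It does not model
between-feature biology beyond the factor structure above.

## 6. Invasiveness models (`edgescore.invasiveness`)

* **Standardization.** Train-only z-scores; zero-variance training
  columns dropped with a warning. Validation rows never influence the
  scaler (tested by mutation).
* **mRMR.** Greedy MID criterion: relevance = mutual information between
  the label and the quartile-discretized feature; redundancy = mean MI
  with already-selected features; ties keep the earliest column.
  Default k = 20. Implemented as a scikit-learn `SelectorMixin`, verified
  against an independent brute-force replay.
* **Classifiers.** Eight families with library defaults and fixed seeds:
  XGBoost, LightGBM, logistic regression, random forest, AdaBoost,
  decision tree, MLP, SVM (probability outputs). Stratified 80:20 split;
  validation AUC with 2000-replicate stratified-bootstrap percentile CI;
  sensitivity/specificity at the Youden-optimal threshold.
* **Attributions.** Permutation-sampling Shapley values against a
  training background. The telescoping construction makes additivity
  exact per sample: attributions sum to prediction minus mean background
  prediction to float precision. Rankings are mean |φ| over validation
  samples.
* **Cross-validation.** Stratified k-fold with the scaler and selector
  refit inside every fold.

## 7. Survival models (`edgescore.survival`)

* **Cox.** `lifelines` CoxPHFitter, Efron tie handling, Wald CIs.
  Multivariable default covariate set: age, stage II–III, MTV, VPI,
  EPS group. Univariable mode fits each covariate alone. Fits refuse
  fewer than 10 events and collinear designs.
* **Kaplan–Meier.** Product-limit curves per stratum with Greenwood CIs,
  multivariate log-rank test, median follow-up by reverse KM (censoring
  as the event).
* **Nomogram.** Points representation of the multivariable model: each
  covariate's points are `|β|·(x − ref)` scaled so the largest effect
  range spans 0–100, with the reference at the least hazardous observed
  end. Points ↔ linear-predictor mappings are exact inverses; survival
  probabilities come from the fitted baseline at the requested horizon.
* **AUC(t).** Cumulative/dynamic time-dependent AUC with IPCW
  (`scikit-survival`) at 12/36/60 months, bootstrap CIs; horizons without
  prior events or beyond follow-up are flagged, not extrapolated.
* **Calibration.** Decile-binned predicted vs KM-observed survival at a
  horizon, Greenwood CIs per bin; bins with inadequate support are
  flagged.

## 8. Determinism and reproducibility

Every stochastic stage takes an explicit integer seed (< 2³¹) and flows
through `numpy.random.default_rng`; identical seeds give byte-identical
cohorts, phantoms, and model evaluations. CSV feature tables are written
with 17-significant-digit floats and read back with pandas' round-trip
parser, so table round trips are exact. The CLI writes a JSON
run-manifest (package version + SHA-256 of the configuration) beside
every output.

## 9. Known limitations

* The `f = 1.0` EPS oracle case is structurally outside its tolerance
  (see §2); the red test documents this honestly.
* The radiomics manifest follows IBSI-style definitions but is not
  IBSI-phantom certified; it is pinned and versioned so downstream
  feature tables are comparable across package versions.
* The cohort generator draws `nDmaxC` and `nDmaxP` as independent
  log-normals; their joint distribution in real tumors is unknown, so
  the implied EPS median (~0.42) is close to, but not exactly, typical
  reported medians.
* Replicate hazard-ratio recovery is summarized as the geometric mean
  (mean log-HR). The arithmetic mean of fitted HRs is Jensen-biased
  upward by ≈ e^(SE²/2) (~9% at SE ≈ 0.4) even for an unbiased
  estimator, so it is not a faithful recovery summary. A small-sample
  Cox MLE bias of a few percent on the log scale remains visible at
  n = 244.
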