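# edgescore

Edge Proximity Score (EPS) toolkit for FDG-PET of non-small-cell lung
cancer: a spatial biomarker quantifying whether a tumor's metabolic
hotspot (SUVmax voxel) sits near the lesion's edge or its core, together
with the analysis pipeline it is embedded in — semi-automatic
segmentation, conventional and radiomic PET metrics, invasiveness
classification, and progression-free-survival modelling — plus fully
synthetic phantom and cohort generators that make every stage testable
without patient data.

## The score

For a segmented lesion, let `DmaxC` be the Euclidean distance (mm) from
the SUVmax voxel to the lesion's geometric centroid and `DmaxP` the
distance to the nearest lesion boundary. Both are normalized by the
volume-equivalent sphere radius `R_eq = (3V / 4π)^(1/3)`:

```
nDmaxC = DmaxC / R_eq        nDmaxP = DmaxP / R_eq

EPS = (nDmaxC − nDmaxP) / (nDmaxC + nDmaxP)
```

EPS ranges from −1 (hotspot at the exact center) to +1 (hotspot on the
boundary); 0 means equal proximity to centroid and perimeter. Lesions
with EPS > 0 form the high-risk stratum: peripheral hotspots are
associated with histologic invasiveness (lymphovascular invasion,
visceral pleural invasion, spread through air spaces) and shorter
progression-free survival.

## Worked example

Everything below is reproducible offline; the phantom generator provides
analytic ground truth.

```python
from edgescore.synthetic import PhantomSpec, make_phantom
from edgescore.segmentation import segment_lesion, qc_filter
from edgescore.spatial import compute_spatial_features
from edgescore.metrics import conventional_metrics

# Digital sphere (radius 16 mm) with the hotspot at 75% of the radius.
volume, _, truth = make_phantom(PhantomSpec(hotspot_fraction=0.75))

# 40%-of-SUVmax semi-automatic segmentation from a seed click.
mask = segment_lesion(volume, tuple(truth["hotspot_index"]))
print(qc_filter(mask))
feats = compute_spatial_features(volume, mask)
print(f"nDmaxC = {feats.nDmaxC:.3f}  nDmaxP = {feats.nDmaxP:.3f}")
print(f"EPS = {feats.EPS:.3f}  (truth {truth['EPS']})  risk group: {feats.risk_group}")
print(conventional_metrics(volume, mask))
```

Output:

```
QCDecision(accepted=True, reason='segmented volume 15887 voxels >= minimum 64')
nDmaxC = 0.769  nDmaxP = 0.256
EPS = 0.500  (truth 0.5)  risk group: high
ConventionalMetrics(SUVmax=10.0, SUVmean=5.750226622369572, MTV_ml=15.887, TLG=91.3538503495854)
```

Downstream stages run on simulated cohorts:

```python
from edgescore.synthetic import CohortSpec, make_cohort
from edgescore.invasiveness import fit_and_evaluate, shap_rank
from edgescore.survival import cox_fit, km_stratify

cohort = make_cohort(CohortSpec(n=244, seed=1))      # 122 candidate features
evals = fit_and_evaluate(cohort, "LVI", seed=1)      # 8 classifiers, 80:20
best = max(evals, key=lambda e: e.auc)
ranking = shap_rank(best)                            # mean-|Shapley| ranking
cox = cox_fit(cohort)                                # multivariable Cox PH
print(cox.effects["eps_group"].hr)
```

## Command line

The `edgescore` entry point wires the same stages together; every run
writes a JSON run-manifest beside its outputs.

```bash
edgescore phantom --out phantom/                      # volume, mask, truth
edgescore segment --pet phantom/phantom.nii.gz --seed 30,22,22 --out seg.nii.gz
edgescore spatial --pet phantom/phantom.nii.gz --mask seg.nii.gz --out spatial.json
edgescore cohort --n 244 --seed 1 --out cohort.csv
edgescore invasiveness --cohort cohort.csv --endpoint LVI --out lvi.json
edgescore survival --cohort cohort.csv --out survival.json
```

## Package layout

| Module | Contents |
| --- | --- |
| `edgescore.io` | NIfTI volume/mask I/O, CSV feature tables, geometry types |
| `edgescore.segmentation` | 40%-SUVmax seeded segmentation, 64-voxel QC rule |
| `edgescore.spatial` | hotspot location, distances, normalization, EPS, stratification |
| `edgescore.metrics` | conventional metrics; 115-feature radiomics with a versioned manifest |
| `edgescore.synthetic` | digital phantoms with analytic truth; cohort simulator |
| `edgescore.invasiveness` | mRMR selection, 8 classifiers, Shapley attributions, CV |
| `edgescore.survival` | Cox models, Kaplan–Meier, nomogram, AUC(t), calibration |
| `edgescore.cli` | `edgescore` console entry point |

Methodological details and every numerical convention are documented in
[docs/methods.md](docs/methods.md).

## Reproduction

```bash
pip install --no-build-isolation -e ".[test]"
pytest -q                                    # full suite, ~1 minute
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes three pre-registered targets from
scratch: the EPS of an equidistant-hotspot sphere phantom (0 ± 0.05), the
feature count retained by the default selection stage (exactly 20), and
the multivariable EPS-group hazard ratio recovered over 200 simulated
cohorts (geometric mean within ±10% of the generator's 2.667).

One test is expected to fail: the `f = 1.0` arm of the sphere-oracle
sweep in `tests/test_acceptance.py`. With perimeter distance defined as
the distance to the nearest background voxel center — the convention the
distance-transform oracle pins exactly — a hotspot on the boundary always
measures one voxel of perimeter distance, so its EPS error is
`2/(R + 1) ≈ 0.118` at radius 16, above the stated `1.5/16` tolerance for
any possible implementation. The assertion is kept at the stated
tolerance rather than widened; see
[docs/methods.md](docs/methods.md#the-f--10-boundary-case) for the
analysis.
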