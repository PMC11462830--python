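# gliomicro

Multi-model diffusion-MRI microstructure analysis for predicting
postoperative recurrence of lower-grade glioma (LrGG, WHO grade II–III).

Preoperative diffusion MRI probes tumor microstructure through water
displacement. This package re-implements, as a fully tested pipeline, a
multiparametric analysis in which seven reconstruction models are fitted
voxel-wise to two-shell data (b = 0, 1250, 2500 s/mm², 25 directions per
nonzero shell), ROI features are aggregated per patient, compared between
recurrence and non-recurrence groups, and combined into an OPLS-DA
classifier. Because no patient data are distributable, a first-class
synthetic-phantom module generates both signal-level and feature-level
cohorts with known ground truth, so every stage is verifiable end to end.

## Models and metrics

| Model | Fitted quantity | Emitted metrics |
|---|---|---|
| DTI | diffusion tensor D (WLLS, b ≤ 1250) | FA, MD, AD, RD |
| DKI | D + kurtosis tensor W (22-parameter WLLS) | AK, MK, RK |
| WMTI | maximal directional kurtosis | AWF = K_max/(K_max+3) |
| Watson-NODDI | S=(1−V_iso)(V_ic S_ic+(1−V_ic)S_ec)+V_iso S_iso | ICVF, ODI = (2/π)·arctan(1/κ) |
| Bingham-NODDI | as above with Bingham ODF (κ₁ ≥ κ₂) | Bin-ICVF, Bin-ODI, DAI |
| SMI | stick+zeppelin+ball kernel ⊛ ODF, per-shell rotational invariants S₀, S₂, S₄ | f, Da, De∥, De⊥, fw |
| CSD/AFD | fiber ODF by constrained spherical deconvolution of the b = 2500 shell | AFD-max, AFD-sum, AFD-total |

The statistics stage mirrors the clinical analysis: Shapiro-routed
t / Mann–Whitney tests, Pearson chi-square for categorical tables, ROC
with DeLong confidence intervals and paired AUC comparison, and OPLS-DA
with VIP scores, cross-validated Q2Y and a 200-fold label-permutation
overfitting test.

## Worked example

```python
from gliomicro.phantom import CohortConfig, make_cohort
from gliomicro.cohort_stats import metric_table, table2
from gliomicro.oplsda import permutation_test

cohort = make_cohort(CohortConfig(preset="paper-like", seed=1))   # 25 + 23 patients
stats = metric_table(cohort.features, cohort.labels)
print(stats.loc[["MD", "De_perp"], ["test", "pvalue"]])
rep = permutation_test(cohort.X, cohort.labels, n_perm=200, seed=1)
print(f"R2Y={rep.r2y:.3f}  Q2Y={rep.q2y:.3f}  CV AUC={rep.roc_cv.auc:.3f}")
```

prints

```
            test    pvalue
metric
MD        t-test  0.000050
De_perp  welch-t  0.000009
R2Y=0.820  Q2Y=0.660  CV AUC=0.970
```

Mean diffusivity falls and the extra-axonal perpendicular diffusivity
De⊥ falls sharply in the recurrence group (denser tissue restricts water
displacement), so both separate the groups strongly; combining all 21
metrics, the OPLS-DA model explains 82% of the label variance, predicts
66% out of fold, and discriminates the groups with a cross-validated AUC
of 0.97. In the same run the single best metric, De⊥, reaches AUC 0.864
(95% CI 0.762–0.967) and tops the VIP ranking (VIP = 1.50), i.e. the
multiparametric model improves on any single metric. All 200 permuted
models score below the original Q2Y (intercepts R2Y = 0.29,
Q2Y = −0.35), indicating the model is not overfitted.

A command-line interface wraps the same stages:

```bash
gliomicro phantom --preset paper-like --level features --seed 1 --outdir fixtures
gliomicro stats fixtures/features.csv
gliomicro oplsda fixtures/features.csv --n-perm 200
gliomicro run --config run.yaml          # full pipeline with a report bundle
```

## Layout

- `src/gliomicro/protocol_io.py` — gradient schemes, NIfTI/bval/bvec I/O, ROIs, clinical tables
- `src/gliomicro/phantom.py` — compartment signal simulator and cohort generators
- `src/gliomicro/tensor_models.py`, `noddi_models.py`, `smi_model.py`, `fodf_afd.py` — the seven reconstructions
- `src/gliomicro/cohort_stats.py` — ROI aggregation, group tests, ROC/DeLong
- `src/gliomicro/oplsda.py` — OPLS-DA estimator (scikit-learn interface), VIP, Q2Y, permutation test
- `src/gliomicro/pipeline.py`, `cli.py` — orchestration and the `gliomicro` command
- `docs/methods.md` — model details, priors, numerical choices and limitations
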