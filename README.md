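# dtbc — Digital Tumor Bud Count

Tumor budding — small clusters of up to about five tumor cells detached
from the main tumor mass at the invasive front — is a strong adverse
prognostic marker in early oral squamous cell carcinoma (OSCC), but visual
bud grading is poorly reproducible. `dtbc` implements a standardized,
semi-automated digital score and the clinical models built on top of it,
for pathologists and biostatisticians working with cytokeratin
(AE1/AE3) IHC section images and per-patient cohort tables.

## The score

On a calibrated RGB section image with a manually drawn tumor region of
interest (necrosis and salivary glands excluded):

1. the DAB (brown) channel is isolated by optical-density color
   deconvolution (Ruifrok–Johnstone H-DAB vectors) at a reduced analysis
   magnification, and thresholded;
2. every 8-connected stained region gets a unique label and an area
   *A* in µm² from the pixel calibration;
3. regions with *A* < 150 µm² are discarded as staining artifacts;
4. with a nominal tumor-cell cross-section of 190 µm², regions with
   150 µm² ≤ *A* < *n*·190 µm² are counted as tumor buds (default
   *n* = 5 cells, ceiling 950 µm²).

The number of bud-sized regions is the **Digital Tumor Bud Count
(DTBC)**. A sweep utility re-counts every patient under ceilings of
*n* = 1…20 cells to examine how bud size relates to prognosis.

## The clinical layer

* **Nodal-risk model** — binary logistic regression of occult lymph-node
  metastasis on DTBC and clinicopathological covariates, with forward
  likelihood-ratio selection, apparent and stratified 10-fold
  cross-validated AUC (DeLong CIs, selection re-run per fold), and
  Hosmer–Lemeshow calibration.
* **Decision-curve analysis** — net benefit of model-guided neck
  dissection vs treat-all/treat-none over threshold probabilities, and
  the net reduction in unnecessary neck dissections per 100 patients:
  NB = TP/n − (FP/n)·p_t/(1−p_t).
* **Survival** — DTBC tertiles, Kaplan–Meier with at-risk tables at
  0/1/3/5 years, log-rank tests, and Cox proportional-hazards models
  (Efron ties) with forward entry + conditional removal.
* **Synthetic data** — stained-section phantoms with exact per-island
  ground truth, and cohort simulators with known logistic/proportional-
  hazards structure, so every stage is testable without patient data.

## Worked example

The published worked example labels three tumor islands of 890, 885 and
1297 µm². Scoring them with the defaults:

```python
from dtbc import classify_buds, regions_from_areas

res = classify_buds(regions_from_areas([890.0, 885.0, 1297.0]))
print(res.dtbc, res.region_areas_um2)
# 2 [ 885.  890. 1297.]
```

Two islands are buds (885 and 890 µm², both under the 950 µm² ceiling);
the 1297 µm² island is counted as tumor mass, not a bud.

End-to-end on generated data:

```bash
dtbc demo --out demo_out --seed 7
```

scores three phantoms and a simulated 1000-patient cohort. Output
(abridged):

```
"phantoms": [{"phantom": 0, "truth_buds": 6, "dtbc": 6, ...}, ...]
"risk_model": {"variables": ["dtbc_tertile", "depth_mm", "pni"],
               "apparent_auc": 0.716, "cv_auc": 0.707,
               "hosmer_lemeshow_p": 0.439}
"logrank_os_by_tertile": {"chi2": 63.2, "df": 2, "p": 1.9e-14}
"cox_os_selected": ["dtbc_tertile", "age", "node_binary"]
```

Every phantom's DTBC equals its constructed ground truth; the stepwise
Cox model recovers exactly the covariates that carry hazard in the
generator; the Hosmer–Lemeshow p of 0.44 indicates no detectable
miscalibration. Other subcommands: `score`, `sweep`, `simulate`,
`riskmodel`, `dca`, `survival` (see `dtbc <cmd> --help`).

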