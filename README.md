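# kbplan

Knowledge-based IMRT planning toolkit for nasopharyngeal carcinoma (NPC):
predict achievable organ-at-risk (OAR) dose–volume histograms from patient
anatomy, turn the predictions into starting optimization objectives, refine a
training database by flagging suboptimal prior plans, and score finished
plans with a 200-point banded plan-quality metric.

## Who this is for

Medical physicists and dosimetrists building or studying knowledge-based
planning (KBP) pipelines. Manual IMRT planning is trial-and-error: the
achievable OAR doses are unknown before optimization and depend strongly on
each patient's geometry. KBP predicts, from prior high-quality plans, what
DVH each OAR *should* be able to reach for a new anatomy, and seeds the
optimizer with patient-specific objectives instead of generic templates.

## The model

For each OAR, the anatomy is summarized by

- **volumetric features** — OAR volume, target volume, the fraction of the
  OAR overlapping the PTV, and the OAR-to-body volume ratio; and
- **spatial features** — the *distance-to-target histogram* (DTH): the
  cumulative fraction of OAR volume within each signed Euclidean distance of
  the PTV surface (negative inside the target).

DTH and DVH curves, sampled on common axes (DVH in relative dose, 0–110% of
the prescription), are parameterized by principal component analysis; 1–4
components capture more than 97% of the variance of each curve family. A
multivariate linear regression selects the statistically significant
features per DVH score, and one ε-insensitive support vector regression
(RBF kernel) maps features to each retained DVH score. Predictions carry a
95% band built from out-of-fold training residuals, so

    lower95  ≤  predicted mean DVH  ≤  upper95     (pointwise, by construction)

Objectives are read off the **lower bound** of the band (maximal sparing
pressure) — except for OARs adjacent to or overlapping the target (optic
chiasm, optic nerve, pituitary, inner ear) in advanced T3/T4 cases, which
use the **predicted mean** so target coverage is not sacrificed.

Plan quality is scored with banded dosimetric indices over four organ
levels — targets (100 pts), critical (60), sub-critical (25), other normal
organs (15), total 200 — including the Paddick conformity index
CI = (V_Tref/V_T)·(V_Tref/V_ref) and the homogeneity index
HI = (D_2% − D_98%)/D_50%.

A synthetic phantom module generates cohorts of PTV+OAR geometries with a
parametric exponential dose falloff, D = Rx·exp(−λ·d), so the DTH→DVH
relationship is known by construction and the entire pipeline is testable
without patient data.

## Worked example

Generate a 20-case phantom cohort, train a DVH model, predict a held-out
case, and emit objectives:

```bash
kbplan phantom --n 20 --seed 5 --out cohort/
kbplan train --manifest cohort/manifest.csv --out model.json --flag-suboptimal
kbplan predict --model model.json \
    --oar cohort/case000_oar.nii.gz --target cohort/case000_ptv.nii.gz \
    --body cohort/case000_body.nii.gz --t-stage T3 --out pred/
kbplan objectives --predictions pred/ --t-stage T3 --out objectives.csv
```

which prints

```
wrote 20 cases to cohort
flagged suboptimal cases: []
trained on 20 cases -> model.json
wrote prediction for oar to pred
wrote 7 objectives to objectives.csv
```

`pred/oar_mean.csv` is the predicted achievable DVH with its band in
`oar_lower95.csv` / `oar_upper95.csv`; no case in this homogeneous cohort is
flagged as suboptimal. `objectives.csv` contains one upper DVH-point
objective per OAR at 2/30/50/70% volume (read off the lower95 curve, since
this OAR is not in the adjacent set) plus lower DVH-point objectives for the
targets at their prescriptions (70/60/54 Gy at 98%).

Scoring a plan:

```python
from kbplan.phantoms import scoring_reference_case
from kbplan.plan_quality import compute_plan_metrics, default_score_table, score_plan

masks, dose, prescriptions = scoring_reference_case()
table = default_score_table()
result = score_plan(compute_plan_metrics(masks, dose, table, prescriptions), table)
print(result.total)          # 200.0
print(result.subtotals)      # {'targets': 100.0, 'critical': 60.0,
                             #  'subcritical': 25.0, 'other': 15.0}
```

The ideal conformal phantom (each target uniformly at its prescription,
every OAR unirradiated) lands every table entry in its best band, hence the
maximum 200 points.

## Layout

| module | contents |
| --- | --- |
| `kbplan.core_grid` | voxel grids, structure masks, dose grids, resampling |
| `kbplan.histograms` | cumulative DVH/DTH computation, curve CSV I/O |
| `kbplan.curve_embedding` | PCA parameterization of curve families |
| `kbplan.dvh_model` | features, selection, ε-SVR training/prediction, refinement flagging |
| `kbplan.objectives` | objective generation with the mean/lower-bound strategy switch |
| `kbplan.plan_quality` | CI, HI, D/V indices, the 200-point score table |
| `kbplan.phantoms` | synthetic cohorts with known geometry→dose structure |
| `kbplan.io`, `kbplan.config`, `kbplan.cli` | NIfTI/NRRD/DICOM-RT I/O, run config, CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults, and
known limitations.
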