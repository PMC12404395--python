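# aneumorph

Morphometry, wall-field summaries, and a staged statistical workflow for
intracranial-aneurysm rupture-risk assessment.

## Scientific problem

Whether an intracranial aneurysm is likely to rupture is assessed from
the geometry of the sac and from the hemodynamic and structural loads on
its wall. Coupled blood-flow / wall-mechanics simulations produce
time-resolved surface fields (wall traction, pressure, displacement,
stress tensors) on a triangulated vessel surface; clinical practice
additionally uses scalar shape descriptors of the sac. The analysis
problem this package addresses is the *post-processing side* of such a
study:

1. reduce a labeled surface mesh to morphological descriptors — size
   `S`, aspect ratio `AR`, size ratio `SR`, volume-to-ostium-area ratio
   `VOR`, sac volume `V`, and the Gaussian-curvature L2 norm `GLN`, a
   dimensionless surface-irregularity index that is 1 for a sphere and
   grows with lobulation;
2. reduce one cardiac cycle of surface fields to hemodynamic and
   structural summaries — maximal/average wall shear stress (WSS),
   oscillatory shear index (OSI), transmural pressure, relative wall
   displacement, and von Mises stress;
3. run a six-stage statistical workflow over a three-group cohort
   (ruptured / unruptured / stable): nonparametric screening,
   collinearity pruning, logistic-regression odds ratios, composite
   risk scores, ROC threshold selection, and internal validation of the
   frozen thresholds on an independent ruptured-only set.

Because patient data cannot ship with the code, the package also
contains synthetic generators — meshes with closed-form curvature and
volume oracles, analytic pulsatile field series, and copula-sampled
cohort tables — that exercise every stage against known answers.

## Model summary

- **Discrete Gaussian curvature** at a vertex is the angle deficit
  divided by the mixed Voronoi area (obtuse-safe); on a closed genus-0
  mesh the deficits sum to 4π exactly (Gauss–Bonnet), which the test
  suite verifies to 1e-9 relative.
- **GLN** = √(A · Σᵢ Kᵢ² Aᵢ) / 4π over the sac region: scale-invariant,
  1 for a sphere, > 1 for any other closed genus-0 surface.
- **OSI** = ½(1 − ‖∫τ dt‖ / ∫‖τ‖ dt) with trapezoidal time integration;
  0 for unidirectional shear, 0.5 for symmetric reversal.
- **Workflow**: Mann-Whitney U screening (exact enumeration for small
  tie-free samples), greedy |ρ|-descending collinearity pruning at a
  0.75 cutoff, maximum-likelihood logistic fits with Wald 95% CIs and
  explicit non-estimability flags under complete separation, fixed
  composite products (WG, GD, WGD), ROC thresholds chosen as the
  maximal-specificity point with sensitivity ≥ 0.8, and strict-greater
  threshold validation.

See `docs/methods.md` for the full methods note, parameter conventions,
and limitations.

## Worked example

```python
import numpy as np
from aneumorph import (ShapeSpec, make_mesh, make_field_series, morphometry,
                       summarize, CohortSpec, make_cohort, run_workflow)

# 1. morphometry of a hemispherical sac (r = 2 mm) with parent tube
mesh, ostium, _ = make_mesh(ShapeSpec(kind="hemisphere-on-cylinder",
                                      radius=2.0, parent_radius=1.5,
                                      subdivisions=5))
shape = morphometry(mesh, ostium)
print(f"S   = {shape.S:.3f} mm")
print(f"AR  = {shape.AR:.3f}")
print(f"GLN = {shape.GLN:.3f}")

# 2. one cardiac cycle of synthetic wall fields, reduced to summaries
series, _ = make_field_series(mesh, waveform="pulsatile", seed=0)
hemo = summarize(series, mesh)
print(f"WSS_max = {hemo.WSS_max:.3f} Pa   OSI_max = {hemo.OSI_max:.4f}   "
      f"MISES_max = {hemo.MISES_max:.2f} kPa")

# 3. the full six-stage workflow on a seeded synthetic cohort
cohort, validation = make_cohort(CohortSpec(seed=7))
report = run_workflow(cohort, validation)
print("retained after pruning:", report.retained_after_prune)
print(report.roc.round(3))
```

Output:

```
S   = 4.000 mm
AR  = 0.501
GLN = 0.480
WSS_max = 11.414 Pa   OSI_max = 0.0727   MISES_max = 934.71 kPa
retained after pruning: ['WSS_max', 'OSI_max', 'OSI_min', 'D_rel_max', 'MISES_max', 'AR', 'V', 'GLN']
       AUC  threshold  sensitivity  specificity  target_met  direction
WG   0.957      0.418        0.931        0.933        True          1
GD   0.933      2.397        0.810        0.933        True          1
WGD  0.944      0.634        0.931        0.933        True          1
```

(A hemisphere is half a sphere, so its dome GLN is about 0.5; closed
sacs have GLN ≥ 1.)

The same pipeline is available from the command line:

```bash
aneumorph simulate --seed 1 --out-dir work/
aneumorph morph --mesh work/mesh.vtk --ostium work/ostium.json --out work/morph.csv
aneumorph workflow --cohort work/cohort.csv --validation work/validation.csv \
    --out-dir work/report/
```

## Reproduction

All headline quantities — geometry and field oracle errors, statistical
oracle agreements, and the workflow's AUCs, thresholds, validation
sensitivities, and replicate-study rates — are recomputed by:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The run is deterministic in `--seed`; every reported entry carries the
sample size it was computed from.
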