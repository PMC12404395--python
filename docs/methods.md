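# Methods note

## Scope

The package post-processes the outputs of coupled blood-flow /
wall-mechanics simulations of intracranial aneurysms: labeled surface
meshes, time-resolved wall fields, and cohort tables of the derived
parameters. The simulations themselves are out of scope; their outputs
are consumed (or emulated by the synthetic generators).

Units throughout: mm for lengths, Pa for wall shear stress, kPa for
pressure and solid stress, seconds for time.

## Mesh model

A surface is a vertex/face triangle mesh with per-vertex region labels
(`PARENT = 0`, `SAC = 1`, `NECK = 2`). Validation rejects out-of-range
face indices, zero-area faces, non-manifold edges (an edge on more than
two faces), and inconsistent winding (a directed edge appearing twice).
The ostium is a simple boundary loop plus a fitted plane (least-squares
via SVD, normal oriented toward the sac centroid); its area is the
projected-polygon area and its equivalent diameter is that of the
equal-area circle.

## Morphometry

- **Gaussian curvature** `K_i` at vertex `i` is the angle deficit
  `2π − Σ θ` divided by the mixed Voronoi area (cotangent formula with
  the standard obtuse-triangle fallback). Boundary vertices get `NaN`.
  On closed genus-0 meshes the deficits sum to 4π (Gauss–Bonnet); the
  tests check this to 1e-9 relative.
- **GLN** `= √(A · Σ K_i² A_i) / 4π` over non-boundary sac vertices,
  with `A` the summed sac area. Dimensionless and scale-invariant;
  equals 1 for a sphere and exceeds 1 for every other closed genus-0
  surface (Cauchy–Schwarz against Gauss–Bonnet). For open dome patches
  it is the same expression on the patch, so a hemisphere scores ≈ 0.5.
- **Volume** `V` by the divergence theorem over the dome faces plus a
  centroid-fan cap across the ostium; closedness of the capped surface
  is checked, retrying with flipped winding.
- **Size** `S`: maximal pairwise distance between sac vertices (convex
  hull first). **AR**: dome height above the ostium plane divided by
  the ostium equivalent diameter. **SR**: `S` over the parent-vessel
  diameter (mean equal-area-circle diameter of the parent boundary
  rings, or a user override). **VOR**: `V` over ostium area.

## Field summaries

A field series holds traction (Pa), pressure (Pa), displacement (mm),
and Voigt-6 stress (kPa, order xx yy zz xy yz zx) on ≥ 3 strictly
increasing time samples. Reductions over the sac region:

- WSS: per-vertex traction magnitude; `WSS_max` (peak over time and
  vertices), `WSS_av` (time-mean, then vertex-mean), `WSS_rel_max`
  relative to the parent's peak.
- OSI `= ½(1 − ‖∫τ dt‖/∫‖τ‖ dt)` with trapezoidal integration, clipped
  to [0, 0.5]; zero-shear vertices score 0.
- Pressure is shifted so the global minimum is zero, then reported in
  kPa (max / time-average / min over the sac).
- `D_rel_max`: peak sac displacement over peak parent displacement.
- von Mises stress from the Voigt components; `MISES_max`, `MISES_av`.

## Statistical workflow

Six stages over a cohort table (`id`, `group` ∈ {ruptured, unruptured,
stable}, 18 parameter columns), with the primary contrast ruptured vs
stable:

1. **Screening** — two-sided Mann-Whitney U per parameter and group
   pairing; the exact null distribution when min(n) ≤ 8 without ties,
   otherwise the tie/continuity-corrected normal approximation.
   Parameters with p < α (default 0.05) on the primary pairing are
   retained; zero-variance columns are dropped with a warning.
2. **Collinearity pruning** — Pearson |ρ| on the primary-pair subset;
   pairs above the cutoff (default 0.75) are resolved highest-|ρ|
   first, keeping the member with the smaller screening p (lexicographic
   tie-break), so the outcome is independent of column order.
3. **Logistic regression** — univariate and multivariate ML fits
   (Newton, tolerance 1e-8, ≤ 100 iterations). Internally predictors
   are z-scaled for conditioning and the coefficients/SEs rescaled back,
   which is exact (the MLE is affine-equivariant); reported ORs are per
   raw unit unless `standardize=True` (per SD). Fits that do not
   converge, hit perfect separation, or produce |β| or SE beyond 50 on
   the z-scale are flagged `estimable = False` with NaN OR instead of a
   divergent number. Which predictors enter the multivariate model is
   controlled by `multivariate_entry`: the default
   `"univariate_significant"` co-enters only estimable,
   univariate-significant predictors (staged model building, which also
   reduces — but cannot eliminate — separation of the joint model);
   `"pruned"` enters everything that survived stage 2.
4. **Composites** — fixed products `WG = WSS_rel_max · GLN`,
   `GD = GLN · D_rel_max`, `WGD = WSS_rel_max · GLN · D_rel_max`.
5. **ROC / thresholds** — the curve is swept over all observed score
   values with strict-greater classification; AUC by trapezoid (equal
   to the normalized U statistic on tie-free data). The operating
   threshold is the maximal-specificity point among those with
   sensitivity ≥ the target (default 0.8); ties go to maximal Youden J,
   then to the smallest threshold; if the target is unreachable the
   maximal-Youden point is used with a warning. Scores with AUC < 0.5
   are auto-flipped and the direction recorded.
6. **Internal validation** — the frozen thresholds are applied to an
   independent ruptured-only table; sensitivity is the fraction of
   scores strictly above the threshold.

Runs are deterministic given (inputs, config); the report carries a
config hash, every stage warning, and serializes to JSON and Markdown.

## Synthetic data: what it does and does not emulate

**Meshes** (`make_mesh`) come with closed-form oracles: icospheres
(area, volume, constant K, GLN = 1), scaled ellipsoids (GLN by an
independent tensor-grid quadrature of the analytic curvature),
degree-3 spherical-harmonic lobulated sacs (GLN strictly above the
sphere's), and a hemispherical sac with its equator as the ostium plus
a disjoint parent tube (volume, S, AR, VOR, parent diameter all
analytic).

**Field series** (`make_field_series`) are analytic per-vertex closures
(steady, reversing, non-reversing, pulsatile waveforms) sampled on the
requested time grid; the OSI oracle evaluates the same closures on a
20001-point grid, so reduction error can be measured directly.

**Cohorts** (`make_cohort`) draw lognormal marginals (mean-calibrated,
single coefficient of variation, default 0.4) through a Gaussian
copula whose default correlation carries a near-unity WSS pair and
moderate within-block structure, so the pruning stage is genuinely
exercised.

They do **not** emulate: real vessel anatomy or segmentation noise,
physiologic waveform shapes beyond simple harmonics, per-parameter
dispersion differences (the single CV is a deliberate simplification —
no per-parameter spreads are available to calibrate against), missing
data, or inter-parameter relations beyond second-order (copula)
structure.

A consequence of the single-CV design worth knowing: parameters whose
group means differ by large ratios become near-perfect discriminators,
and the ruptured-vs-stable subcohort is then usually completely
linearly separable. The multivariate logistic MLE does not exist under
complete separation, and the workflow reports exactly that (per-
coefficient `estimable = False`) rather than pseudo-significant
coefficients. On such cohorts the multivariate-significant set is
therefore typically empty — visible in the replicate rates reported by
`scripts/acceptance.py`.

## Numerical choices

- Mixed Voronoi areas use the cotangent formula with the obtuse
  fallback (T/2 at the obtuse corner, T/4 otherwise).
- All time integrals are trapezoidal on the given grid.
- Quadrature oracles (ellipsoid GLN, dense OSI) are refinements of the
  defining integrals, independent of the pipeline's reduction code.
- Copula sampling uses a Cholesky factor; non-positive-definite
  correlation matrices are rejected, not repaired.
- Legacy ASCII VTK polydata is parsed natively (token stream with
  line-numbered errors) and carries the vertex labels as a point-data
  scalar; STL/PLY go through `trimesh` (STL vertices are re-merged).

## Limitations

- Morphometry assumes a manifold, consistently wound triangle mesh and
  a simple, nearly planar ostium loop; highly non-planar necks are
  rejected rather than approximated.
- GLN on open dome patches depends mildly on where the dome is cut;
  values are comparable only under a consistent labeling convention.
- Wald confidence intervals and p-values are asymptotic; with 15
  records in the smallest group they are rough, and under separation
  they are (correctly) not reported at all.
- The ROC threshold is selected on the primary cohort and validated
  only on ruptured-only data, so specificity is never externally
  validated — matching the internal-validation design, not replacing a
  prospective one.
- Synthetic cohorts are calibrated in their means and correlation
  pattern only; none of the empirical AUCs, thresholds, or
  sensitivities computed on them should be read as clinical estimates.
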