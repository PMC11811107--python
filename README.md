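# wingmorph

Landmark-based geometric morphometrics for discriminating moth species by
forewing venation.

Pheromone traps set for the invasive looper moth *Chrysodeixis chalcites*
cross-attract large numbers of native plusiines — above all *Chrysodeixis
includens* — and every trapped specimen must be identified. `wingmorph`
implements the landmark pipeline that makes this screening quantitative:
seven landmarks digitized around the forewing discal cell (a region that
survives trap damage) are superimposed by generalized Procrustes analysis,
and group differences are tested and exploited for classification in the
resulting tangent shape space.

## What it computes

For configurations of *k* = 7 two-dimensional landmarks:

- **Centroid size** CS = √Σᵢ‖xᵢ − x̄‖², the standard size measure.
- **Generalized Procrustes analysis (GPA)**: every wing is centred, scaled
  to unit centroid size and rotated onto an iteratively refined consensus
  (reflections disallowed — all wings are right forewings); the ensemble is
  aligned to the consensus principal axes and projected orthogonally into
  the tangent space at the consensus, of dimension 2k − 4 = 10.
- **Shape PCA** of the tangent covariance matrix.
- **Allometry**: multivariate regression of shape on centroid size;
  `% predicted` = 100 · SS_model/SS_total, with a permutation test.
- **Procrustes ANOVA**: one-way ANOVA of centroid size, and Goodall's
  F = [SS_B/((g−1)(2k−4))] / [SS_W/((n−g)(2k−4))] for shape, with
  parametric and permutation p-values.
- **Canonical variate analysis (CVA)** in the full-rank PCA subspace, with
  pairwise Mahalanobis and Procrustes distances and permutation tests.
- **Screening**: a frozen CVA classifier that assigns unknown wings to
  species by Mahalanobis distance, with an ambiguity flag and leave-one-out
  cross-validation.
- **Synthetic data**: a generator of realistic raw landmark datasets
  (template mean shapes, isotropic digitizing noise, lognormal sizes,
  optional allometry, similarity jitter) for validating every stage.

The API follows the model/results pattern: each analysis is a class whose
`fit()` returns a results object with a `summary()`; functional shortcuts
(`gpa`, `shape_pca`, `procrustes_anova`, `cva`, …) wrap them.

## Worked example

```python
import wingmorph as wm

# two species-like templates a Procrustes distance 0.13 apart
base, widened = wm.template_pair(0.13)
spec = wm.SyntheticSpec(
    templates={"C_includens": base, "C_chalcites": widened},
    n_per_group={"C_includens": 24, "C_chalcites": 23},
    noise_sigma=0.03,
    size_shift_per_group={"C_chalcites": 0.12},
    seed=7,
)
dataset = wm.simulate_labeled(spec)
aligned = wm.gpa(dataset)
print(wm.procrustes_anova(aligned, n_perm=9999, seed=1).summary())
print(wm.cva(aligned, n_perm=9999, seed=1).summary())
print(wm.cross_validate(dataset).summary())
```

prints

```
Procrustes ANOVA (classifier: species; groups: C_chalcites, C_includens)
  effect          SS          df        F         P
  centroid size   38068       1         19.65     5.919e-05
  size error      87189       45
  shape           0.14828     10        18.89     4.978e-29 (permutation: 0.0001)
  shape error     0.3532      450

Canonical variate analysis (classifier: species)
  groups: C_chalcites, C_includens
  canonical variates: 1
    CV1: eigenvalue 5.775, 100.0% of between-group variation
  overall Goodall F: 18.8919 (P = 4.978e-29)
  Procrustes distances among groups:
             C_chalcites  C_includens
C_chalcites       0.0000       0.1128
C_includens       0.1128       0.0000
  permutation P (9999 rounds):
             C_chalcites  C_includens
C_chalcites       0.0000       0.0001
C_includens       0.0001       0.0000

Leave-one-out cross-validated classification
  overall accuracy: 97.9%   (ambiguous calls: 1)
  confusion matrix (rows true, columns predicted):
             C_chalcites  C_includens
C_chalcites           23            0
C_includens            1           23
```

Reading the numbers: the two simulated species differ significantly in
both wing size (F = 19.65 on 1 and 45 df) and wing shape (Goodall
F = 18.89 on 10 and 450 df; the permutation p of 1/10000 is the smallest
the (b+1)/(N+1) convention allows). With two groups the CVA has a single
canonical variate carrying all between-group variation, and the Procrustes
distance between the group mean shapes (0.113) estimates the generating
template separation (0.13, shrunk slightly by within-group sampling).
Leave-one-out screening calls 46 of 47 wings correctly.

The same pipeline is scriptable from a shell:

```sh
wingmorph simulate --spec spec.yaml --out sim.tps --meta sim.csv
wingmorph import --tps sim.tps --meta sim.csv --out dataset.json
wingmorph gpa --in dataset.json --out aligned.json
wingmorph analyze --aligned aligned.json --nperm 10000 --seed 1 --out results.json
wingmorph screen fit --aligned aligned.json --out model.json
wingmorph screen predict --model model.json --tps unknowns.tps --out calls.csv
```

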