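# Methods

## The model

Chemical bioactivity is modulated by genome-wide target binding, but observed
chemical–protein interaction data are one-class (only positives are
recorded), extremely sparse, and biased.  This package represents each
chemical by its **latent target interaction profile (LTIP)**: its row of the
low-rank factor `U` obtained by factorizing the binary interaction matrix
`R` (n chemicals × m proteins) under

```
min_{U,V}  Σ_ij P_wt(i,j) (R(i,j) + P_imp(i,j) − U_i·V_j)²
         + p_reg (‖U‖²_F + ‖V‖²_F)
         + p_chem tr(Uᵀ (D_c − C) U)
         + p_prot tr(Vᵀ (D_T − T) V)
```

where `C` and `T` are chemical–chemical and protein–protein similarity
matrices with degree matrices `D_c`, `D_T`.  Observed cells carry weight
`P_wt = 1` and imputation `P_imp = 0`; unobserved cells carry a uniform
weight `w_unobserved ∈ [0,1]` (how strongly an absent link is treated as a
negative) and a uniform imputed value `imp_unobserved ∈ [0,1]` (a prior
belief that some absent links are latent positives).  The two Laplacian
terms force similar chemicals and similar proteins toward nearby latent
rows; they are the only information source for a *cold-start* chemical with
no observed targets, which is the situation of a novel chemical entering a
QSAR model.

The elementwise weight/imputation construction is deliberately uniform.  A
per-entry neighborhood-based construction exists in the literature but is
not reproduced here; uniform values keep the objective's one-class
acceleration exact (see below) and cover the weighted/imputed semantics.  An
optional two-pass scheme (`impute_refit=True`) re-fits once after imputing
the top `impute_top_frac` of unobserved predictions (clipped to [0, 1]) as
soft positives.

## Solver

Alternating **Gauss–Seidel exact row minimization**.  With everything else
fixed, row `i` of `U` minimizes a quadratic whose normal equations are

```
(Σ_j P_wt(i,j) V_jᵀV_j + (p_reg + p_chem d_i) I) u
    = Σ_j P_wt(i,j) A(i,j) V_j + p_chem Σ_j C(i,j) U_j ,   A = R + P_imp
```

a k×k solve.  Because the uniform unobserved weight collapses
`Σ_j P_wt V_jᵀV_j` to `w·VᵀV` plus a sparse correction over the row's
observed entries, one sweep costs `O((n+m)k² + (nnz(R)+nnz(C)+nnz(T))k)`
rather than `O(nmk)`.  Rows are updated in ascending index order using
already-updated rows (Gauss–Seidel, not Jacobi), so every row update is an
exact block minimization and the recorded loss trace is non-increasing by
construction — the property the convergence tests assert.  The same holds
for the loss itself, which is evaluated in closed form
(`nm·a² − 2a·ΣU·ΣV + ⟨UᵀU, VᵀV⟩` plus sparse corrections) without
materializing `U Vᵀ`.

Numerical choices:

- all accumulation in double precision;
- factors initialized `uniform(0, 0.01/√k)` from the configured seed, so
  initial scores sit near zero (the one-class prior) and runs are bitwise
  reproducible;
- convergence when the relative per-sweep loss decrease drops below
  `rel_tol` (default 1e-4) or after `max_sweeps` (default 100);
- a singular row system (possible only with all penalties zero and no data
  in the row) receives a 1e-10 ridge and a logged warning;
- rank default 600 for a full-scale chemical–protein network; desk-scale
  problems and all tests use the planted rank (2–10).

Cold-start chemicals enter either **jointly** (augment `R` with an all-zero
row and `C` with the query's similarity column, then fit — the default,
matching the incorporate-then-factorize schema) or by **fold-in** (solve
only the new rows of `U` against frozen factors; exact for the same row
equations, much cheaper, used for scoring against an existing model).

## Similarity graphs

- Chemical similarity: Tanimoto coefficient `|A∩B|/|A∪B|` over binary
  fingerprint on-bits; an all-zero pair scores 0.
- Protein similarity: pairwise alignment bit-scores normalized by the
  geometric mean of the two self-scores, clipped to [0, 1]; asymmetric
  score tables are symmetrized by taking the larger direction first.  The
  normalization rule is this package's choice — alignment scores admit
  several sensible normalizations and none is canonical.
- Similarities are stored with a zero diagonal.  Self-loops cancel in
  `D − S`, so this is loss-equivalent and avoids double bookkeeping.
- Optional top-k row sparsification (union-symmetrized, k=100 suggested at
  full scale, unlimited in tests) keeps Laplacian terms tractable.

## QSAR benchmarking protocol

For each cell line, a regressor maps chemical features to drug-response AUC:

1. split the chemicals into training/development and hold-out test sets
   (default 124/20 out of 144, seeded);
2. select hyperparameters on the training set by leave-one-out
   cross-validation, scored by squared error on each left-out chemical
   (a correlation is undefined on a single point, so MSE is the selection
   metric); ties break toward the earlier grid point;
3. refit on all training chemicals and report the Pearson correlation
   between predicted and observed AUC on the hold-out set;
4. compare feature sets by mean correlation across cell lines and by mean
   rank (rank 1 = best within a (cell line, model) group, ties averaged,
   undefined correlations excluded from means and ranked worst).

Models: SVR, k-nearest-neighbors (KNR), random forest (RF), extra trees
(RF_EXTR), gradient boosting (XGB).  SVR and KNR receive in-pipeline
feature standardization fitted on training folds only; tree ensembles
consume raw features.  Cell-line genomic features are excluded so that the
chemical representations are compared on equal footing.  SVR carries a
default libsvm iteration cap (`max_iter=20000`, overridable): uncapped
libsvm can crawl on noisy, barely-separable data at larger `C` while the
fit itself is unchanged to three decimals.

Default grids (all config-overridable) are compact, covering kernel/C for
SVR, neighborhood size and weighting for KNR, tree count, feature fraction
and leaf size for the forests, and depth/learning-rate/estimators for XGB.

## Synthetic worlds

The generator plants the structure the method assumes, so the whole
pipeline is testable without any external database:

- `U_true`, `V_true` (n×r, m×r): each entity belongs to one of r latent
  archetypes; its archetype coordinate is `uniform(0.8, 1.2)` and the rest
  `uniform(0, 0.1)`.  Non-negative, cluster-dominated factors.
- `R`: the planted scores `U_true V_trueᵀ` thresholded at the quantile that
  yields the requested density (default 2% of a 200×100 matrix — about 1.6
  links per chemical, emulating the severe sparsity of curated interaction
  data).  A held-out fraction (default 20%) of the positives is removed
  from `R` for link-recovery evaluation.
- `C`, `T`: cosine similarity of the true factor rows plus symmetric
  Gaussian jitter (sd 0.05), clipped to [0, 1], zero diagonal.
- responses: for each of 7 pseudo-cell-lines, `y = U_true β + ε` with
  `β ~ N(0, 1)` per line and noise sd 0.1 by default (the latent signal has
  roughly unit scale, so this is a ~10% noise floor; evaluation of the
  noiseless regime sets sd = 0).  Responses depend on the *latent* factors,
  not on raw structure — the central hypothesis that the target interaction
  profile correlates with bioactivity more directly than structure does.
- fingerprint control: 64 bits, each assigned to an archetype; a bit is on
  with probability 0.8 for chemicals of its archetype and 0.1 otherwise,
  then flipped with probability 0.1.  The control therefore sees a noisy
  cluster signal but none of the continuous within-cluster variation — a
  caricature of the activity-cliff problem of structural fingerprints.

All randomness flows from a single seed through one `numpy` generator.

What the generator does **not** emulate: real chemistry (no SMILES), assay
bias and batch structure, heavy-tailed interaction degrees, dose–response
curve shapes (AUC is drawn directly), and correlated noise across cell
lines.  Passing tests therefore show that the machinery behaves as designed
in the regime it assumes — not that the representation outperforms real
fingerprints on real data.

### Analysis configuration for planted worlds

`synthetic.default_fit_config` fits at the planted rank with `p_reg=0.05`,
`p_chem=p_prot=2.0`, `w_unobserved=0.1`.  At ~1.6 observed links per
chemical the similarity graphs carry most of the signal, so the Laplacian
weight is set high enough that data-poor chemicals inherit their
neighborhood's latent position; the ridge is light, and the unobserved
weight is the usual one-class compromise between treating absences as
negatives and ignoring them.  This was chosen once as the package's analysis
configuration for the planted regime and is used by all end-to-end tests
and the acceptance script.

### Problem sizes

End-to-end checks run at the generator defaults (200×100, rank 5): link
recovery over 10 world seeds, the benchmark over 7 cell lines × 2 feature
sets × 2 fast regressors (SVR, KNR) with compact grids, and a 50-replicate
permutation null.  These sizes make the full suite a few minutes of
single-core compute while keeping every measured effect far from its
decision threshold.  Tree-ensemble LOOCV at n=124 is much slower per grid
point and is exercised in unit tests at small n instead.

## Known limitations

- The solver provides a linear embedding only; no non-negativity
  constraints, no stochastic solver, no per-entry confidence weighting
  beyond the uniform scheme.
- At very low density the planted score *ordering* is not identifiable from
  one-class observations (most of the ordering concerns unobserved cells);
  identifiability is checked at density 0.2, and the sparse regime is
  evaluated by held-out link recovery instead.
- Joint embedding of queries refits the whole model; fold-in is exact only
  for the query rows against frozen factors.
- The LOOCV protocol refits n_train models per grid point; it is meant for
  the benchmark's small-n regime (~10² training chemicals), not for large
  training sets.
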