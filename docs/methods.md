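# Methods

## The synthetic cohort generator

`modfuse.datasets.generate_multimodal` draws a multimodal dataset whose
statistical shape mirrors a single-site imaging-genomics cohort of the
HC → MCI → AD progression.

* **Classes.** Three ordered diagnostic groups with configurable counts;
  the default cohort is 47 HC / 93 MCI / 49 AD.
* **Continuous modalities** (MRI 93, PET 93, CSF 3 features by default).
  Feature *j* of modality *m* is Gaussian with standard deviation
  `noise_sd` (default 1, unitless — features are normalized downstream).
  A planted informative feature shifts its mean by
  `c · effect_sizes[m] · noise_sd` for class code `c ∈ {0, 1, 2}`, i.e. a
  Cohen's-d-like effect per disease step, linear along the progression.
  The default effect size is 1.0 per step: adjacent contrasts are
  moderately hard, the extreme AD-vs-HC contrast (d ≈ 2) is easy — the
  difficulty ordering seen in real cohorts.
* **Genotypes** (189 SNPs by default). Each SNP gets a minor-allele
  frequency drawn uniformly from `snp_maf_range` (default (0.05, 0.5]);
  genotypes are Binomial(2, p_c) minor-allele counts. Informative SNPs
  shift the MAF on the logit scale, `logit(p_c) = logit(p_0) + c · effect`,
  which keeps genotypes on their {0, 1, 2} support for any effect size.
  The drawn baseline MAFs are stored on the dataset (`snp_maf`) as ground
  truth for generative-model checks.
* **Reproducibility.** One root seed spawns an independent child stream
  per modality, so the same spec is bit-reproducible and modalities are
  statistically independent of one another.

What the generator deliberately does **not** emulate: linkage
disequilibrium between SNPs, spatial correlation between imaging regions,
site/batch effects, missing genotypes, and label noise. Passing tests on
this generator therefore demonstrate correctness of the estimators and
protocol, and recoverability of planted signal under clean conditions —
not performance on real cohort data, where correlated features and
weaker, non-additive effects will reduce every method's accuracy.

## Unsupervised screening scores

Both scores take a features × samples matrix and return finite scores
with a deterministic descending ranking (ties broken by ascending feature
index).

* **Laplacian score** `s(k) = XₖLXₖᵀ / XₖDXₖᵀ` on the full all-pairs
  heat-kernel graph `W_ij = exp(−‖xᵢ−xⱼ‖²/σ)`; no kNN sparsification is
  applied because cohort sizes are small (hundreds). The ratio is
  evaluated exactly as written; the classical D-weighted centering of each
  feature is available behind `centered=True` for users who want the
  textbook variant. Features with zero denominator score 0, and tiny
  negative values from round-off are clipped to 0 (the Laplacian is PSD).
  σ is a free bandwidth parameter (default 1) — the score is known to be
  sensitive to it, which is one motivation for the LGD alternative.
* **LGD score** — global variance over summed local variance:
  numerator Σᵢ(xᵢ(k) − x̄(k))², denominator
  Σⱼ Σ_{xᵢ(k) ∈ o(xⱼ(k))} (xᵢ(k) − x̄ⱼ(k))² + ε, where `o(xⱼ(k))` is the
  m values nearest to xⱼ(k) (self included, ties by ascending sample
  index) and x̄ⱼ(k) their mean. The neighborhood size m defaults to 5 and
  is exposed as a parameter. The +ε guard (default 1e-8, as everywhere a
  denominator could vanish) keeps locally-constant features finite and
  sortable rather than mapping them to infinities.

The SNP pre-screen in the protocol keeps the top-k (default k = 189) LGD-
ranked SNPs, fitted inside each training fold.

## Normalization

Three train-fitted schemes, applied per feature:

* **z-score** — subtract the training mean, divide by the training
  *population* standard deviation (1/N inside the root, not 1/(N−1)) + ε.
  Used for MRI, PET and CSF.
* **min–max** — subtract the training minimum, divide by the training
  range + ε. Used for genotypes; test values may leave [0, 1], which is
  accepted rather than clipped.
* **unit-ball** — divide by the feature's ℓ2 norm over training rows + ε.
  Applied to the concatenated feature vector as the final step, so no
  feature dominates by scale. Re-applying it is a no-op up to ε effects.

All statistics are computed from training rows only and reused verbatim
on held-out rows.

## The learners

### Multiple kernel learning

One linear basis kernel per feature coordinate by default (so the learned
simplex weights β form a per-feature relevance profile and the per-feature
weight vector needed for downstream element-wise weighting falls out
directly); a per-modality grouping is available through the `groups`
argument. The solver alternates (i) an exact soft-margin SVM on the
composite kernel Σₘ βₘKₘ (libsvm on a precomputed kernel, tolerance 1e-8)
with (ii) the closed-form update βₘ = ‖wₘ‖₂ / Σₖ‖wₖ‖₂ — the minimizer of
Σₘ‖wₘ‖²/(2βₘ) over the ℓ1 simplex at fixed w, with the convention
0/0 → 0. Both half-steps decrease the objective; a step that fails to
decrease it (numerical exhaustion) terminates the loop with the previous
iterate, so the objective trace is non-increasing by construction.
β starts uniform at 1/M (unbiased; also preserves the symmetry of
duplicated kernels).

### High-order graph-matching regularized selection (HGM-FS)

Objective over the coefficient matrix W (d × L):
fit ‖WᵀX − Y‖²_F, entrywise ℓ1 penalty λ₁‖W‖₁ (the standard matrix
extension of the LASSO), pairwise penalty λ₂B and triplet penalty λ₃T as
defined in the README. Targets are encoded ±1 (one row for binary, one-
vs-rest rows for multiclass), matching the SVM label convention used
elsewhere in the package.

Numerical notes:

* B collapses to `2N‖(Y − WᵀX)H‖²_F` with H the column-centering
  projector — an algebraic identity with the double loop, verified
  against it in the tests.
* T sums over **all ordered triples, repeated indices included** (their
  terms are well defined; most vanish). Writing M = YᵀY − (WᵀX)ᵀ(WᵀX),
  the summand is (M_ij − M_ik − M_jj + M_jk)², a quartic polynomial in W
  that collapses to O(N²) statistics of M (row/column sums, diagonal,
  Gram totals). Small problems (N ≤ 60) evaluate the triple sum
  explicitly; both paths agree to round-off and both are tested against
  a literal triple loop. The gradient is assembled analytically through
  M and validated against central finite differences (relative error
  < 1e-5), which is the key correctness gate for this term.
* Solver: monotone FISTA from W = 0 — accelerated proximal gradient with
  backtracking (halve the step until the quadratic model upper-bounds the
  smooth part), soft-thresholding for the ℓ1 term, and a fallback to the
  plain proximal step whenever the extrapolated candidate fails to
  decrease the objective. The sufficient-decrease argument makes every
  accepted step lower the full objective even though T is nonconvex, so
  the trace is monotone; on nonconvex instances the contract is the
  objective value (checked against multi-start derivative-free
  minimization), not a particular stationary point.
* Stopping: absolute decrease < `tol`, or relative decrease
  < `rtol · |initial objective|` (the cross-validation pipeline uses
  rtol = 1e-7 so large fits stop when converged relative to scale).
* Selection: features whose row of W has any entry above `select_tol`
  (default 1e-6 — "non-zero coefficient" needs a numerical threshold);
  the per-feature weight profile is the row-wise ℓ2 norm.

### Sparse multimodal learning (SMML)

The convex program
min_W ΣᵢΣₚ(1 − y_pi·w_pᵀxᵢ)₊ + γ₁ΣₚΣ_q‖w_p^q‖₂ + γ₂‖W‖₂,₁ over
modality-blocked coefficients. The exact display of this objective varies
across the sparse-multimodal-learning literature (in particular whether
the group penalty acts on (modality × class) blocks or modality rows, and
how the class hinges are weighted); **the objective stated here, with
uniformly weighted class hinges and (modality × class) groups, is this
module's contract**, and the tests verify global optimality of the solver
for exactly this program. No bias term is included; append a constant
feature to emulate one.

Solver: the hinge is Huber-smoothed (quadratic on [0, μ]) and each group
norm smoothed as √(‖·‖² + δ²) − δ with δ = μ; the smooth surrogate is
minimized by L-BFGS under a continuation schedule μ = 1e-1 → 1e-7 that
warm-starts each stage from the best iterate so far. A stage is accepted
only if it lowers the *exact* nonsmooth objective, so the recorded trace
is non-increasing and the returned W is the best exact-objective point
seen. The smoothing error is bounded by N·L·μ/2 (hinge) plus γ·δ per
group, far below the 1e-4 agreement demonstrated against an independent
cone-program solve on small instances. Selection uses row norms with
`select_tol = 1e-6`; `smml_block_norms` reports ‖w_p^q‖₂ per
(modality, class) — a zero block means that modality plays no role in
that class's decision function.

## The classification protocol

For each (modality configuration, task, method) cell:

1. restrict to the task's subjects (binary contrasts use two classes; the
   three-class task uses all);
2. split into stratified 10 folds (fixed seed; stratification is not part
   of the original protocol description but keeps every class present in
   each fold at cohort sizes of 50–200);
3. per fold, on training rows only: LGD pre-screen of the SNP block to
   top-189, per-modality normalization, unit-ball scaling of the
   concatenation, selector fit, element-wise feature weighting, linear
   SVM (libsvm, tolerance 1e-6);
4. evaluate the held-out fold: accuracy / sensitivity / specificity for
   binary tasks (the first-named class is positive; an undefined rate is
   reported as NaN with a warning, never silently 0), argmax over three
   one-vs-rest decision values for the multiclass task (ties go to the
   lower class in HC < MCI < AD order).

For multiclass selection, HGM-FS and SMML fit one multi-column model
whose row norms are shared by the three one-vs-rest SVMs; MKL is fitted
per one-vs-rest task and the per-feature profiles are averaged into a
single shared weight vector.

**Grid search** evaluates every hyperparameter cell on the same fold
partition and reports the best mean-accuracy cell (ties: first cell in
deterministic key order). This "best reported performance" convention
carries an optimistic bias; `run_cv(..., nested=True)` provides the
unbiased alternative that re-selects the cell inside each training fold.
Default grids are log-spaced: C ∈ 10^{−3..3}; λ and γ parameters
∈ 10^{−4..1}; `QUICK_GRIDS` provides reduced grids (3 values of C; λ₃
fixed at 0, since the triplet penalty dominates runtime at cohort scale
while its correctness is established by the small-scale oracle tests).

## Problem sizes used in the shipped studies

The test suite and `scripts/acceptance.py` exercise the pipeline at
deliberately chosen scales: oracle equivalence on hundreds of random
instances at d ≤ 10, N ≤ 30 (scores) and N ≤ 8 (triplet terms); solver
optimality on ~20-variable convex instances; and the protocol studies on
(i) a recovery cohort of 200 subjects per class with 10 planted features
per modality at effect 1.5 and (ii) the default 47/93/49 cohort at the
full 93+93+3+189 dimensionality. Planted-SNP recovery is scored on the
genotype-only configuration: in the joint four-modality fit the imaging
features separate the classes by themselves, so a sparse joint model can
correctly ignore the redundant SNPs — support recovery is only
identifiable where the planted features are not redundant.

## Known limitations

* The generator's independence assumptions (above) make selection easier
  than on real data; recovery rates and accuracies are upper bounds on
  what correlated cohorts would give.
* SimpleMKL-style alternating minimization is guaranteed monotone but not
  guaranteed to reach the global optimum of the joint problem; the tests
  bound its objective against an exhaustive simplex grid on small
  problems.
* The HGM-FS objective is nonconvex whenever λ₃ > 0; different platforms
  may reach different stationary points of equal quality.
* The non-nested grid search is optimistically biased by construction;
  use `nested=True` when an unbiased performance estimate matters more
  than protocol fidelity.
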