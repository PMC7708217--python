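# Methods

## The model

A methylation profile over a genomic region is a vector of beta values
y = (y_1, …, y_I) in [0, 1] at CpG coordinates x = (x_1, …, x_I).  After
rescaling coordinates affinely onto [−1, 1], the profile is modelled as a
linear combination of Gaussian radial basis functions,

    y_i ≈ Σ_j w_j exp(−δ (x_i − μ_j)²),   i.e.  y ≈ H w,

with J centers μ_j equally spaced over [−1, 1].  Defaults are J = 50 and
δ = 10 (some sources quote the scale as γ = −10 inside exp(γ r²); δ is the
same quantity stored as a positive rate).

Profiles are grouped into units — the N subjects within one region
(regional model) or the M regions within one subject (subject model) — and
units are assumed to fall into K latent clusters with mixing proportions
π_k.  Given its cluster, a unit's observed values are independent Gaussians
around the cluster curve H w_k with a shared noise variance σ².  Because J
can exceed the number of observed points per cluster, the weights carry an
l1 penalty weighted by cluster size, giving the penalized log-likelihood

    L(θ) = Σ_n log Σ_k π_k Π_i N(y_in ; H(x_in) w_k, σ²)  −  λ Σ_k π_k ‖w_k‖₁ ,

maximized over θ = {π, w_1..K, σ²} by EM:

* E-step: responsibilities ẑ_nk ∝ π_k Π_i N(y_in ; H(x_in) w_k, σ²),
  computed in log space.
* M-step: π_k = mean_n ẑ_nk; each w_k solves a responsibility-weighted
  lasso whose coordinate-wise soft threshold is λ π_k σ², by cyclic
  coordinate descent on the precomputed per-unit Gram blocks (at most 50
  passes per EM iteration, warm-started across iterations, so the M-step is
  a monotone partial maximization); σ² is the pooled weighted residual
  variance (floor 1e−6).  At λ = 0 the weight update solves the normal
  equations exactly.

The penalized objective is non-decreasing across iterations up to the
convergence tolerance (relative change 1e−6, at most 200 iterations).
Clusters whose total responsibility falls below 1e−6 are dropped and K
reduced.  Each fit runs 5 restarts (seeds seed..seed+4): k-means++ on
ridge-smoothed per-unit curves for the first restarts, random assignments
for the last two, keeping the best penalized log-likelihood.  Units are
processed in a canonical feature-sorted order inside the initializer and
the CV fold assignment, which makes results invariant to subject/region
ordering.

## Model selection

λ is chosen per K by 10-fold cross-validation: observed points are
partitioned into folds within each unit (units with a single point are
never held out), held-out points are predicted from the fit on the rest,
and the squared error summed; ties resolve to the smallest λ.  Within each
fold the λ grid is fitted as a descending warm-started path, and CV fits
are capped at 40 EM iterations — measured against full-length fits this
changes the selected models not at all while cutting a third of the
runtime.  The default grid is 8 values log-spaced in [1e−3, 30] × sd(y).
The wide upper end is deliberate: the effective soft threshold is
λ π_k σ², so with σ² near the noise floor (~0.02–0.04) a useful amount of
shrinkage needs λ well above the data's standard deviation; cross-validated
error is unimodal inside this grid, whereas a grid capped at 1 × sd(y)
truncates the optimum.

K runs over 1..K_max with K_max = max(2, ⌊N/5⌋) capped at 10 (at least ~5
expected units per cluster), and the fit with the lowest ICL is retained:

    ICL = −2 ℓ̂ + p log(n_units) − 2 Σ_nk ẑ_nk log ẑ_nk ,

with ℓ̂ the unpenalized maximized log-likelihood and p the number of
*active* (nonzero) RBF weights plus K − 1 mixing proportions plus one
variance — the degrees-of-freedom convention of l1-penalized mixture
regression.  The BIC sample size is the number of units, since the mixture
draws are units, matching model-based-clustering practice.  Counting all
K·J weights against log(total points) instead (available via
`icl_score(df="all", n_basis="points")`) makes the penalty dwarf any
likelihood gain at these problem sizes and collapses selection to K = 1
regardless of the true structure; with the active-coefficient convention,
selection on 4-cluster data lands on K ≥ 4 and over-specified K behaves
like the true K, as expected for this model family.

## Imputation and stacking

A missing position is imputed from the unit's hard-assigned cluster curve
(argmax ẑ_nk, ties to the lowest index; posterior-weighted mixing available
as `assignment="soft"`), clipped to [0, 1].  A unit with no observed points
gets the π-weighted population curve and is flagged.

The regional and subject predictions ŷ_r, ŷ_s at each missing cell are
combined as β_r ŷ_r + β_s ŷ_s with β ≥ 0 fitted by non-negative least
squares (no intercept; an intercept variant exists behind a flag).  The
training pairs come from bootstrapped artificial masking: each of 100
replicates hides 10% of the observed cells (disjoint from the truly missing
ones), runs both models, and solves the NNLS problem at the hidden cells;
the final weights are the means over replicates.  The printed constraint
β > 0 is implemented as β ≥ 0 so the minimum is attained; exact zeros are
reported.  Weights are global for the dataset (per-region weights behind a
flag).

## Region definition and filtering

* Adjacent clustering: bottom-up merging of neighbouring CpGs/regions while
  the gap is < 3000 bp and the average cross-region pairwise Pearson
  correlation is > 0.3; the best adjacent pair merges first, ties to the
  leftmost, constant sites count as correlation 0.
* Sliding windows of 50 CpGs (trailing remainder dropped with a warning)
  and promoter pruning to the 25 CpGs flanking a TSS on each side.
* Filter gates: > 15 subjects with data, pooled variance > 0.1, pooled
  adjusted Fisher–Pearson skewness > −1, and < 15 runs.  The runs variable
  is the across-subject mean profile dichotomized at its median (a maximal
  streak on one side of the median is a run); the spatial-pattern reading
  of the gate is configurable but this is the default.  Variance and
  skewness pool all observed values of the region; a per-site variant is
  available by flag.

## The simulator

The generator draws, per region, K = 4 weight vectors i.i.d. standard
normal, forms their curves on 50 equally spaced positions with the J = 50,
δ = 10 basis, and rescales each curve affinely into [0.05, 0.95] so it is a
probability profile with visible dynamic range.  Subjects are assigned
clusters from Multinomial(π = 0.1/0.2/0.3/0.4) independently per region;
Gaussian noise (default sd 0.2) is added to the probabilities and values
clipped to [0, 1]; a fixed fraction of cells per subject is masked by
exact-count subsampling.  All randomness flows from a single seed.  Twelve
shipped configs span the benchmark grid (N ∈ {20, 50, 100, 200},
noise sd ∈ {0.1..0.9}, missing ∈ {0.2..0.8}).

What the generator does not emulate: read-depth (binomial) sampling,
strand effects, spatially correlated noise, or realistic CpG spacing
(positions are equally spaced, which matches the model's scaled-coordinate
view).  A smooth-profile generator (one random cubic-spline curve per
region shared by all subjects, Beta-distributed subject noise,
concentration 30) is included as a synthetic stand-in for profile-based
read simulators; it deliberately violates the mixture assumptions and is
used for misspecification tests only.  Passing tests on these generators
demonstrate correct behaviour of the algorithmic pipeline under its own
assumptions, not performance on real bisulfite data.

## Evaluation

Per subject, hidden cells are pooled over regions and scored by RMSE
(√(Σ(y−ŷ)²/n)), pooled Pearson correlation, and ROC AUC with the truth
binarized at 0.5 (imputed values enter as raw scores; one-class truth or
constant vectors yield missing values rather than arbitrary numbers).
Methods are compared by paired two-sided t-tests across subjects (paired
because the same subjects are scored under every method; unpaired by flag).

## Problem sizes and expected accuracy

The shipped end-to-end checks run at reduced scale: 20 regions × 50 CpGs ×
20 subjects for the headline 80%-deletion recovery (three seeds), 4
regions with a coarsened λ grid for the method-ordering sweeps, and 10
regions × 20 subjects for the baseline degradation sweep over the
20–80% missing-rate grid.  At the headline condition the
noise itself bounds what any imputer can achieve: imputing every cell with
the exact generative curve yields a pooled correlation of ≈ 0.84 against
the deleted (noisy) values, and an oracle given the true cluster labels
and an oracle-tuned regularizer reaches ≈ 0.82.  The full pipeline
(ICL-selected K, CV-selected λ) measures ≈ 0.77 — the residual gap is
cluster-assignment and curve-estimation error from the ~10 observed points
per subject per region.

## Numerical choices

* Ridge 1e−8 stabilizes unpenalized normal-equation solves (the RBF Gram
  at J = 50, δ = 10 is numerically singular); callers asking for ridge = 0
  on a rank-deficient system get a typed error rather than garbage.
* Coordinate-descent tolerance 1e−8 on the largest coordinate change.
* σ² floor 1e−6 guards noise-free fixtures against likelihood blow-up.
* Predictions are clipped to [0, 1] by default (`clip=False` available):
  the linear model is unconstrained but methylation is a proportion.
* bedGraph levels are auto-detected as percent when a file's maximum
  exceeds 1, then divided by 100; an explicit flag overrides.
* Coordinates are 1-based inclusive internally; bedGraph's 0-based
  half-open intervals are converted on read/write.

## Known limitations

* The subject model assumes regions share curve shapes within a subject;
  on data without such sharing it adds noise, and the stacking weights
  shrink its contribution accordingly — on region-structured data the
  regional model alone is often the better choice.
* Model selection is local: EM restarts tame but do not eliminate local
  optima, and at high missingness (few points per unit) the selected K is
  occasionally below the generative K.
* Read counts are not modelled; beta values are treated as Gaussian within
  [0, 1], which is inaccurate near the boundaries.
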