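# Methods

## Problem and model

An expression quantitative trait locus (eQTL) is usually sought as a marker
that shifts the *mean* expression of a gene. `netcov` targets a different
signal: markers whose genotype changes the *co-expression structure* of a
gene set — the covariance matrix of a pathway's genes differs between
genotype classes. Biologically this captures, e.g., post-transcriptional
regulation that rewires the correlation between a transcription factor's
targets without moving any single gene's mean.

For a pathway with expression vector (X₁,…,X_p) and a marker splitting the
samples into genotype groups with covariances Σ₁ and Σ₂ (and possibly Σ₃),
the hypotheses are

    H₀: Σ₁ = Σ₂        vs        H₁: Σ₁ ≠ Σ₂

tested through the squared Frobenius norm tr((Σ₁−Σ₂)²). Its unbiased
estimator is

    T = A₁ + A₂ − 2·C₁₂

where A_h estimates tr(Σ_h²) from sums of products of inner products
x_i′x_j over pairwise-distinct sample indices within group h (three terms
with denominators n(n−1), n(n−1)(n−2), n(n−1)(n−2)(n−3)), and C₁₂
estimates tr(Σ₁Σ₂) from the analogous four-term cross-group sums. Because
only distinct-index tuples enter, no fourth-moment plug-in bias appears
and the test remains usable with p larger than the group sizes. The
denominators require every group to have at least 4 samples (hard floor);
the scan imposes a practical minimum of 10 by default.

For three genotype classes the statistic is T₁₂ + T₂₃ over groups ordered
by ascending genotype code. This pairing does not target an alternative
confined to Σ₁ ≠ Σ₃ with Σ₂ equal to both; power against that corner case
is reduced by construction.

### Kernelized statistic (HSDCC)

Replacing every inner product by a kernel evaluation k(x_i, x_j) gives an
unbiased estimator of the squared Hilbert–Schmidt norm of the difference
between the two covariance *operators* in the kernel's RKHS
(||Σ_xx − Σ_yy||²_HS, the Hilbert–Schmidt Different Covariance Criterion).
The first A-term and first C-term use the squared kernel value; the
combinatorial structure is otherwise identical, so both statistics share
one Gram-matrix code path and the linear kernel reproduces the linear
statistic exactly. The RBF kernel k(x,y) = exp(−‖x−y‖²/(2σ²)) is
parameterized by the bandwidth σ (γ = 1/(2σ²) accepted as an alternative);
σ ∈ {1, 10} are the two bandwidths carried through the analyses and the
CLI defaults. Kernel statistics detect covariance changes that are
nonlinear in the original coordinates (e.g. correlation between
transformed expression levels), at the price of some power in the purely
linear regime.

### Mean adjustment

Markers acting as ordinary (mean) eQTL would contaminate the covariance
comparison, so expression is first residualized: each gene is regressed on
all markers jointly with an L1 (Lasso) penalty, the penalty chosen by
k-fold cross-validation (k = 5 default, fold assignment fixed by the
seed), and residuals are re-centered to exact zero mean per gene — the
centering the U-statistics assume. Markers are standardized before the
fit (default on); constant markers are dropped; missing genotype calls
are mean-imputed per marker *for the design matrix only* (the scan itself
drops missing samples per marker). A gene with zero variance yields an
all-zero residual row with a warning.

### Significance: permutation, NT, FDR

1. **Permutation null.** Genotype labels are permuted B times (default
   1000) and the statistic recomputed; permuting labels rather than genes
   preserves the gene–gene correlation structure, so the null is "no
   genotype effect on covariance". Group sizes are preserved exactly. The
   nominal p-value uses the plus-one rule p = (1+#{T_b ≥ T})/(B+1).
2. **Normalization.** NT = T divided by the mean of the same-sign null
   values (sign-preserving), making statistics comparable across gene
   sets of different sizes and invariant to rescaling. If the null
   contains no value of the needed sign NT is undefined (NaN) and the
   module is excluded from FDR with a warning.
3. **Tail-ratio FDR.** q_raw(v) = (fraction of pooled null NT ≥ v) /
   (fraction of observed NT ≥ v), clipped to [0,1]; the reported q is the
   minimum of q_raw over all thresholds t ≤ v (the Storey q-value
   convention), which makes q monotone non-increasing in NT. The null NT
   pool aggregates all modules and permutations; FDR is computed per
   method (linear, rbf:1, rbf:10) separately, so each method's selected
   set has its own FDR.

Per-module permutation streams are derived by hashing (master seed,
pathway, marker), so adding, removing or reordering modules never
perturbs another module's null, and serial and parallel execution give
identical results.

## Scan pipeline

For every (pathway, marker): pathway genes are intersected with the
expression matrix (skip if fewer than `min_pathway_genes` = 3 survive);
samples with a missing call at that marker are dropped; samples are split
by genotype code (skip if monomorphic or any class below
`min_group_size` = 10). One pooled Gram/kernel matrix is computed per
(pathway, method) and permutations only reindex it — the main cost saving
of the implementation. Results are written sorted by q ascending (ties:
NT descending, then pathway, marker). `select_modules` retains q ≤
`fdr_threshold` (default 0.25, in the range of FDR levels typical for
this kind of module selection).

## Simulation studies

**Moving-average models (linear vs kernel).** Column k of an n×p draw is
f(Z_k) + θ·f(Z_{k+1}) with i.i.d. standard normal latents (p+1 columns, so
no wrap-around) and f = identity / cube / exponential for models 1/2/3.
θ = 0.5 defines the null; the alternative keeps group 1 at 0.5 and sets
group 2 to 0.2 or 0.3. Under model 1 the population covariance is
tridiagonal (diagonal 1+θ², off-diagonal θ), which the generator tests
verify by Monte Carlo. Default grids (p, n₁, n₂) = (40, 60, 60) and
(80, 120, 120).

**Covariance-perturbation models (Frobenius vs max-type).** Base
covariance Σ = D^{1/2} Σ* D^{1/2} with Σ*_ij = 0.5^|i−j| and d_ii ~
Unif(0.5, 2.5); symmetric perturbation U with 8 (sparse, models 1–2) or
500 (dense, models 3–4) nonzero off-diagonal cells at random positions,
magnitudes Unif(0, 4) or Unif(0, 400) × max_j σ_jj with random signs; and
Σ₁ = Σ + δI, Σ₂ = Σ + U + δI with δ = |min(λ_min(Σ+U), λ_min(Σ))| + 0.05,
guaranteeing positive definiteness (λ_min ≥ 0.05). By default the nonzero
count is total cells (mirrored pairs count as two); a flag selects the
once-counted reading. p = 50 and n = 50 per class by default.

**Max-type comparator.** For each covariance entry the standardized
squared difference (s₁ᵢⱼ − s₂ᵢⱼ)² / (θ̂₁ᵢⱼ/n₁ + θ̂₂ᵢⱼ/n₂) with
θ̂ᵢⱼ = mean over samples of ((x_i−x̄_i)(x_j−x̄_j) − sᵢⱼ)² and 1/n
covariances; the statistic is the maximum over entries and the p-value
comes from the type-I extreme-value limit
P(M − 4 log p + log log p ≤ t) → exp(−exp(−t/2)/√(8π)). Known to be
mildly conservative at n = 50. Zero-variance entries are excluded with a
warning. Max-type tests win against sparse alternatives (few large entry
changes); the Frobenius-norm statistic wins against dense ones — the
power harness reproduces both orderings.

**Power harness.** For each model×method, `reps` null datasets and `reps`
alternative datasets are generated; the rejection threshold is the
empirical (1−α) quantile of the null statistics (raw-statistic
calibration — running B permutations inside a 500-replicate power loop
would be prohibitive and is unnecessary, since permutation calibration is
validated separately). ROC curves sweep the threshold over all observed
values, anchored at (0,0) and (1,1). Default 500 replicates per
condition; the full grid of the original studies used 1000, available by
argument.

## Synthetic scan fixture

`make_planted_scan_dataset` emulates a mean-adjusted segregant dataset:
20 unit-variance Gaussian genes, 60+60 samples, 10 balanced binary
markers, 5 pathways of 8 genes. One causal (pathway, marker) pair is
planted: under the alternate genotype the causal pathway's genes acquire
a dense exchangeable correlation ρ = 0.5 (tr((Σ₁−Σ₂)²) = 14 on the
block), the dense regime the Frobenius statistic targets. The generator
does **not** emulate marker linkage, mean-eQTL effects, heavy-tailed
noise or overlapping regulatory programs, so passing recovery tests shows
the pipeline's mechanics and ranking behavior, not field performance on
real segregant data.

## Numerical choices

- Distinct-index sums are evaluated from Gram matrices by
  inclusion–exclusion over coincident indices (O(n²) per statistic);
  correctness is pinned to a literal nested-loop oracle at ≤ 1e-10
  relative error in the test suite, for both kernels.
- Statistics never re-center data internally; centering is the adjustment
  module's contract.
- All randomness flows through `numpy.random.default_rng`; per-module
  seeds are SHA-256 hashes of (seed, pathway, marker) reduced mod 2³¹.
- Ties in result ordering are broken deterministically (NT descending,
  then IDs) so output files are byte-reproducible under a fixed seed.

## Problem sizes used in the shipped checks

The acceptance checks run the calibration study at 200 replicates with
B = 200 permutations (p = 40, n = 60+60), the power comparisons at 500
replicates per condition, and planted-module recovery over 20 generator
seeds at B = 500 — sizes chosen so the full validation completes on a
single CPU in minutes while leaving Monte-Carlo error well inside the
asserted margins.

## Known limitations

- Three-group testing uses the (1,2)+(2,3) pairing only (see above).
- The kernel bandwidth is not selected automatically (no median
  heuristic); σ ∈ {1, 10} must be supplied.
- The FDR is a pooled tail-ratio estimate, not a proof of FDR control;
  with few modules the pooled null is grainy.
- SCAD or other non-convex penalties for mean adjustment are not
  provided; covariates other than markers are not modeled.
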