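# Methods

## Null model

For two independent random vectors x, y ∈ ℝⁿ with normal marginals, the
sample Pearson correlation ρ(x, y) has the density ∝ (1 − ρ²)^((n−4)/2) on
[−1, 1]; equivalently ρ² ~ Beta(1/2, (n−2)/2). The exceedance probability of
its magnitude is therefore

    F(n, p) = P(|ρ| > p) = I_{1−p²}((n−2)/2, 1/2),

with I the regularized incomplete beta function. `null_exceedance_probability`
evaluates this via `scipy.special.betainc`, which carries the log-gamma
arithmetic needed at large n; `1 − p²` is computed as `(1−p)(1+p)` to keep
precision near p = 1. The equivalent trigonometric form

    F(n, p) = [2 Γ((n−1)/2) / (√π Γ((n−2)/2))] ∫₀^{arccos p} sinⁿ⁻³ϑ dϑ

is implemented separately by adaptive quadrature
(`null_exceedance_by_quadrature`) and kept purely as an independent oracle;
the two routes agree below 1e−10 across n ∈ [3, 100], p ∈ [0.01, 0.99]. The
normalizing prefactor is fixed by F(n, 0) = 1 (sources that typeset this
constant ambiguously are thereby resolved). Requirements: n ≥ 3 (the
integrand exponent), p ∈ [0, 1].

Two classical p-value maps for an observed ρ are provided. The Fisher
transform treats arctanh(ρ)·√(n−3) as standard normal (n ≥ 4); the Student-t
map uses t = ρ·√((n−2)/(1−ρ²)) on n−2 degrees of freedom (n ≥ 3) and is
*exact* under normality — `student_pvalue(ρ, n)` equals `F(n, |ρ|)`
identically, a property the tests assert. At |ρ| = 1 both maps return an
exact 0 rather than clipping; threshold computations invert the maps
analytically instead of comparing underflowed p-values.

F is exact for normal data only. For bounded-skewness marginals it remains a
close approximation; simulation with uniform marginals shows the true tail is
a few percent heavier (≈7% relative at n = 15, p = 0.6), which the test suite
documents as an approximation band rather than an exactness claim.

## Thresholds

With m genes there are M = m(m−1)/2 candidate links, and by independence of
the gene pairs' null correlations the thresholded pure-noise network is an
Erdős–Rényi graph with edge probability F(n, p). The secure threshold solves
F(n, p)·M = 1 − ε. The implementation takes the ε → 0⁺ convention as default
(root of F·M = 1, i.e. exactly one expected null edge), which reproduces the
published 5-decimal reference grid; a finite ε is accepted as an option.
Roots are found by `brentq` on the bracket (0, 1) with xtol = 1e−12; the
result matches the direct inversion √(1 − I⁻¹(1/M)) to 1e−9, so it is
independent of bracketing.

The Chebyshev-sharpened threshold p̃ₖ solves F·M + k·√(F(1−F)M) = 1 − ε: the
realized binomial edge count then stays below one except with probability at
most 1/k². p̃₀ = p̄ and p̃ₖ increases strictly in k. Validation is by a
1e−6-step grid scan of the defining inequality and the k-monotonicity
property (no external reference values are available for p̃ₖ).

Bonferroni comparators use the per-link two-sided level p_m = 2α/(m(m−1))
(α = 0.05 gives 0.1/(m(m−1))) and invert the p-value maps in closed form:
ρ = tanh(z_{p_m/2}/√(n−3)) (Fisher) and ρ = t/√(t² + n − 2) (Student-t).
Since the t test is exact, B_t also solves F(n, ρ) = p_m, and the strict
ordering p̄ < B_t holds for every (n, m): the secure threshold tolerates one
expected false edge whereas Bonferroni caps the *probability* of any at 5%.
Two caveats, both verified computationally and asserted in the tests exactly
as they hold:

- The published comparison grid states p̄ < B_F < B_t throughout; in exact
  arithmetic the Fisher comparator dips marginally *below* p̄ at
  (n = 10, m = 1000) and (n = 15, m = 1000), because the normal approximation
  under-covers the extreme tail at small n. The ordering holds at the grid's
  printed 2-decimal resolution, which is how the tests assert it.
- Published threshold tables round their last digit upward (so the printed
  cutoff still guarantees the guarantee); golden tests therefore compare to
  one unit in the last printed digit rather than by round-equality. For the
  20-gene design, two published 3-decimal values (0.799 at n = 10, 0.596 at
  n = 20) are inconsistent with the same machinery that reproduces every
  5-decimal table cell (which gives 0.80191 and 0.59894, implied link count
  ≈ 180 rather than 190); they are treated as source slips and checked at 2
  decimals.

Comparator thresholds are reported even when they exceed 0.99; a threshold
is flagged `unattainable` only when it reaches 1 within 1e−12, meaning no
sub-unit correlation attains the requested level.

## Empty-graph probability: a corrected claim

At p̄ the expected null edge count is 1. Edge indicators are pairwise nearly
independent, so the number of null edges is approximately Binomial(M, 1/M) ≈
Poisson(1) and the probability of a completely empty random network is
e⁻¹ ≈ 0.368 — not ≥ 1/2 as sometimes claimed via a median-of-the-binomial
argument (the median of Bin(M, 1/M) is 1, not 0). Simulation at
(n, m) ∈ {(10, 20), (20, 20), (15, 100)} with 400–4000 replicates gives
0.32–0.37. The acceptance-level test keeps the published ≥ 0.45 bound and
fails by design, recording the measured fractions; the guarantee the secure
threshold actually provides is *one expected* false edge, which is asserted
and holds.

## Graphs

Edges require |ρ| strictly above the threshold (boundary ties excluded), on
the absolute correlation — no signed networks. Gene order follows the input;
edge lists are emitted sorted lexicographically. Rows with zero variance make
the PCC undefined and raise an error naming the gene; subsampling replicates
that produce such a row are redrawn with a logged warning (how degenerate
draws were handled in the original protocol is unstated; erroring loudly and
redrawing is this package's choice).

## Synthetic designs

`generate_block_dataset` builds the 20-gene validation design: two
independent 10-gene blocks over n = 1000 samples (the defaults *are* the
study conditions). Within a block, gene j is built from the block anchor as
G_j = r_j·anchor + √(1−r_j²)·Z_j with i.i.d. normal Z, so the population
anchor correlation is exactly the target r_j — 1 − 0.03j in the first block,
0.7 − 0.015j (global index j) in the second. Only the anchor targets are
specified by the design; correlations between non-anchor genes are the
induced r_i·r_j. Normal marginals are assumed (the null model's hypothesis;
the source leaves the marginal unspecified). The ground truth is the
empirical |PCC| matrix of the generated data with cross-block entries zeroed;
in-block entries are kept real-valued for spectral distances and binarized to
one for link-level confusion — the dual convention used throughout.

`add_noise` perturbs each gene row s by i.i.d. N(0, (α·range(s))²) noise,
reading the noise scale "α·(max−min)" as a per-gene standard deviation;
α ∈ {0.2, 0.4} reproduces the 20%/40% noise conditions.

`generate_two_group_dataset` is the stand-in for a two-module tumour-cohort
structure: groups of 11 and 9 genes, each loading with weight `effect` on its
own latent factor, giving within-group population correlation effect² (0.64
at the 0.8 default) and zero across groups. Its ground truth is the
*population* correlation matrix floored at 0.1 — deterministic, so the true
link count is exactly C(11,2)+C(9,2) = 91. (An empirical truth at n = 161
would stochastically leak cross-group entries past the 0.1 floor; the
population object is the cleaner gold standard for a synthetic stand-in.)

## Evaluation

Confusion ratios follow the all-pairs convention: FP and FN counts are each
divided by m(m−1)/2, so FP-ratio + FN-ratio + (TP+TN)/M = 1. The subsampling
experiment draws n_s of the available samples without replacement, scores
every threshold on the grid 0.01j (j = 1…100) plus the secure threshold
p̄(n_s, m), and aggregates mean ± sd over replicates; replicate r is seeded
as (master_seed, r) so any replicate can be regenerated in isolation.
Defaults follow the original protocol (500 replicates); the acceptance tests
run 100, the package's desk-scale choice.

### HIM distance

The HIM metric is used by the validation protocol but was not defined in the
source describing it; this implementation is a reconstruction from the cited
construction and is flagged as such. Hamming part: mean absolute difference
of (possibly weighted, [0, 1]) adjacency entries over ordered pairs.
Ipsen–Mikhailov part: each graph's Laplacian mode frequencies ω_i = √λ_i
(one trivial zero dropped; extra zeros of disconnected graphs retained) are
broadened into a Lorentzian spectral density normalized on [0, ∞), and IM is
the L² distance of the densities. The width γ is calibrated per node count so
that IM(empty, complete) = 1 (γ ≈ 0.466 for m = 20, cached). Combination:
HIM = √(H² + IM²)/√2, giving 0 iff adjacencies coincide and 1 between the
empty and complete graphs. The density cross-integrals use an exact
residue-calculus closed form for ∫₀^∞ of Lorentzian products, with the
divided-difference log term computed via log1p so nearly coincident
eigenvalues lose no precision; a separately coded adaptive-quadrature oracle
agrees to 1e−8. Exact published HIM curve values are figure-only and are not
asserted anywhere; tests cover endpoints, symmetry, triangle inequality on
sampled triples and the quadrature oracle.

## Problem sizes and numerical choices

Root-finding tolerance 1e−12 on thresholds; quadrature tolerances 1e−14
absolute / 1e−13 relative; oracle-equivalence asserted at 1e−10. Monte-Carlo
checks use 10⁵ null pairs (99% binomial intervals), 300–400 replicates for
density/empty-graph experiments, 100 replicates per subsample size for the
block-design recovery — sizes chosen so every stochastic assertion has
comfortable margin while the whole suite stays interactive. All randomness
flows through `numpy.random.default_rng` with explicit seeds; generators are
bit-reproducible.

## Limitations

- Exactness of F(n, p) requires normal (or near-normal, low-skew) data;
  heavy-tailed or strongly skewed expression values need preprocessing
  (e.g. log transform) before the thresholds are meaningful.
- Correlation is univariate: multivariate dependence among genes (and hence
  edges that only partial-correlation or information-theoretic methods would
  find) is outside the model, and the secure threshold's Erdős–Rényi null
  assumes independent genes.
- The synthetic designs emulate correlation structure only — no probe
  effects, batch effects, missingness or count noise — so passing tests
  demonstrate correctness of the machinery, not robustness to array
  artifacts.
- The secure threshold is intentionally conservative; with generous sample
  sizes it discards true links that looser FDR-style rules would keep.
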