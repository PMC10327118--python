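# Methods

## Model and posterior computation

The observation model is matrix-normal multivariate regression,
`Y = X B + E`, `E ~ MN(0, I_N, V)`, with X (N x J genotypes) and Y (N x R
traits) column-centered; centering is equivalent to integrating out an
intercept under a flat prior, so no intercept appears explicitly. The
residual covariance V is held fixed during fitting.

B is a sum of L single effects, `B = Σ_l γ^(l) ⊗ b^(l)`, with a
multinomial prior on the effect's SNP indicator (uniform π by default) and
a mixture-of-multivariate-normals prior on the effect vector,
`b ~ Σ_k ω_k N(0, σ²_{0l} U_k)`. The patterns U_k and weights ω are fixed
at prior-construction time and shared by all effects; only the scales
σ²_{0l} are fitted.

Conditional on residualized data, one single effect is conjugate: for SNP
j with least-squares summary `bhat_j` and sampling covariance
`S_j = V / (x_j'x_j)`, the per-component posterior is

    logBF_jk = log N(bhat_j; 0, σ²U_k + S_j) − log N(bhat_j; 0, S_j)
    mean_jk  = σ²U_k (σ²U_k + S_j)^{-1} bhat_j
    cov_jk   = σ²U_k (σ²U_k + S_j)^{-1} S_j .

This "σ²U(σ²U+S)^{-1}" form never inverts U_k, which matters because the
canonical patterns (rank-1 trait-specific, all-ones equal-effects) are
singular by construction. All Bayes-factor arithmetic is in log space with
log-sum-exp; with tens of thousands of SNPs the BFs overflow otherwise.
SNP-level quantities follow by mixing: `logBF_j = logsumexp_k(log ω_k +
logBF_jk)`, `α_j ∝ π_j exp(logBF_j)`, and the collapsed posterior moments
obey the law of total variance across components. When the sampling
covariance is shared across SNPs (standardized X, hence the whole z-score
pathway), the per-component posterior covariances are shared too and are
computed once per component rather than per SNP.

The conditional local false sign rate mixes Gaussian tail probabilities
over the posterior component weights:
`clfsr_jr = 1 − max(Pr(b_jr > 0 | γ_j = 1), Pr(b_jr < 0 | γ_j = 1))`.
A component with exactly zero posterior variance in trait r (which occurs
for trait-specific patterns, where the mean is then also exactly zero)
contributes a point mass at zero counted toward neither sign, consistent
with the strict inequalities in the definition.

## IBSS and the ELBO

Fitting is coordinate ascent over effects: residualize out the other
effects through the sufficient statistics (`xtr_l = X'Y − X'X (B̄ − B̄_l)`),
optionally take one EM step on σ²_{0l}, and refresh the single-effect
posterior. Sweeps run in the fixed order l = 1..L; convergence is declared
when the ELBO changes by less than `tol` (default 1e-3) between sweeps,
with `max_iter = 1000` and `L = 10` as defaults.

The ELBO is `E_q[log p(Y|X,B)] − Σ_l KL(q_l || g_l)`, expanded through
`tr(V^{-1}·)` so only X'X, X'Y (and Y'Y for the constant) are needed. One
subtlety: the per-effect KL is evaluated via the residual-likelihood
identity `KL_l = Σ_j α_j [m_j'S_j^{-1}bhat_j − ½ tr(S_j^{-1} E[bb'|j])] −
logBF_model`, which is exact only when q_l is the exact posterior for the
residuals it was computed from. The KL is therefore computed and stored at
refresh time (KL is an intrinsic functional of q_l and the prior, so the
stored value remains valid as other effects move); recomputing it from
end-of-sweep residuals gives a wrong, non-monotone bound. With this
convention the trace is non-decreasing, and for L = 1 the bound is tight:
it equals the exact log marginal likelihood (verified against dense
NR x NR Gaussian densities in the tests). When Y'Y is unavailable (the
z-score pathway) the ELBO is reported up to an additive constant and
flagged; ELBO *differences*, hence convergence behaviour, are unaffected.

### EM for the prior scales

One EM update per (effect, sweep), interleaved before the posterior
refresh. With q_jk = α_j w_jk and pseudo-inverses for singular patterns,

    σ² ← Σ_{j,k} q_jk (m_jk' U_k⁺ m_jk + tr(U_k⁺ C_jk)) / Σ_{j,k} q_jk rank(U_k),

the M-step of EM for the single-effect marginal likelihood; the update is
monotone in that likelihood (tested on random instances, and against a 1-D
grid search in the univariate case). After the update, if the
single-effect log Bayes factor at the new scale does not exceed zero the
scale is set to exactly zero — the null model explains the residuals at
least as well, so this is itself an ascent step. This null check is what
makes automatic relevance determination decisive: unneeded effects are
pruned in one or two sweeps instead of their scales creeping geometrically
toward zero (which also cut the benchmark fit from ~80 sweeps to ~6).
Zero is absorbing within a run; effects start at σ² = 1. Pruned effects
are kept in the fit (for trace reproducibility) but contribute nothing to
posterior means, PIPs, or credible sets.

## Summary-data pathway

For standardized X and Y (`Σx² = Σy² = N`), `X'X = N R̂` and
`X'Y = √N Z̃`, with adjusted z-scores `z̃ = z √(N / (N + z²))`. The
adjustment is odd, monotone, strictly shrinking, and tends to the identity
for small effects or large N. These reconstructions invert exactly when
the z-scores carry the maximum-likelihood (divisor-n) residual variance;
PLINK-style t-statistics (divisor n−2) leave an O(z²/n) gap, ~1e-3 in
PIPs at n = 3,000 and shrinking with n. LD matrices with negative
eigenvalues (rounded or out-of-sample estimates) are spectrally projected
to the nearest PSD correlation matrix before fitting; out-of-sample LD is
accepted with a logged warning since the likelihood is then approximate.
A single shared N is required — per-trait sample sizes are rejected rather
than averaged, because a common-sample design is what makes the LD matrix
shared across traits.

## Priors and residual covariance

The canonical prior contains R + 5 patterns at the default heterogeneity
grid (0.25, 0.5, 0.75): identity, all-ones, R trait-specific rank-1
matrices, and the three constant-correlation matrices, with uniform
weights. The data-driven prior starts from the canonical set plus the
empirical covariance Z'Z/M of per-region top z-scores, up to three rank-1
terms from the SVD of Z, and the rank-3 SVD reconstruction; an optional
`factor_backend` hook can append a sparse low-rank factorization (FL'LF'/M
and per-factor terms) — the default is SVD-only. Extreme Deconvolution
then refines patterns and weights by EM for `z_m ~ Σ_k ω_k N(0, U_k + V)`
(defaults: 500 iterations, tolerance 1e-6 on the mean log-likelihood;
collapsed components are frozen, not deleted; M-step estimates are
symmetrized). Finally a small ridge `eps · I` (default 1e-6 times the mean
diagonal) makes every pattern strictly invertible, protecting the lfsr
computation.

V is estimated from pooled z-scores of SNPs whose largest |z| over traits
is below 2 — approximate nulls — as the mean outer product, then rescaled
to a correlation matrix. Note the |z| < 2 truncation means the estimator
converges to the truncated-normal correlation, which understates strong
residual correlations somewhat (0.32 for a true 0.4 at these settings);
this is a property of the estimator as defined, shared with its reference,
and the tests check it against the truncated-moment integral rather than
against the untruncated truth.

## Summaries

PIPs multiply over active effects only. Credible sets take, per active
effect, the minimal α-descending prefix reaching mass ρ (ties broken by
SNP index for reproducibility); purity is the minimum |LD| over member
pairs (1.0 for singletons) and sets below 0.5 are dropped; the sentinel is
the member with the highest cross-trait PIP. The per-trait CS significance
measure is the α-weighted average of the conditional lfsr over all SNPs,
thresholded at 0.01 by default (a reporting default, configurable). If two
effects yield identical SNP sets both are reported — they represent
additive copies of a signal. Fine-mapping regions are built per trait as
±250 kb windows around hits with p < 5e-8, merged while overlapping, then
merged across traits; coordinates are 1-based inclusive internally and
converted to BED's 0-based half-open convention only in the writer.

## Synthetic data

Real-genotype benchmarks are out of reach at desk scale, so genotypes are
synthetic: two latent Gaussian AR(1) chains (one per haplotype) with lag-1
correlation `ld_decay`, thresholded at per-SNP minor allele frequencies
drawn uniformly from `maf_range`, summed to 0/1/2 dosages. This gives
controllable, smoothly decaying LD and Hardy-Weinberg marginals; it does
not reproduce block LD structure, allele-frequency/LD coupling, or
population stratification. Dichotomization attenuates latent correlation,
increasingly so at extreme MAFs (latent 0.95 yields genotype r ~ 0.65 on
average).

Traits follow the generative recipe of the model itself: draw the causal
count S from {1..5} with probabilities (0.3, 0.3, 0.2, 0.1, 0.1), place
causal SNPs uniformly, draw effects from a sharing prior at unit scale
(canonical prior by default), then solve for the residual variance so the
*largest* per-trait PVE equals the target — 0.05% by default, matching
effect sizes seen in biobank-scale blood-trait analyses. The calibration
uses the population variance of the genetic predictor on standardized
genotypes, so the target is hit exactly rather than in expectation. The
residual correlation C defaults to the identity; `V = σ²C`. Y is centered
and standardized afterward. Only the strongest SNP-trait pair is pinned by
the calibration: with S > 1 the mixture can draw effects of any size,
including effectively zero, so recovery-style claims are only meaningful
per-signal, not per-SNP.

Marginal association statistics are per-(SNP, trait) simple regressions on
centered data with n−2 residual degrees of freedom, and the LD matrix is
`D^{-1/2} X'X D^{-1/2}`. Slopes and z-scores are invariant to column
scaling of X, so centered-only and standardized genotypes give the same
z-scores.

QC utilities mirror common biobank practice: rank-based quantile
normalization to standard-normal scores at (rank − 0.5)/N with averaged
ties, and a multivariate outlier filter removing samples whose Mahalanobis
distance (sample mean and covariance) falls in the upper [0.99, 1]
chi-square quantile of the trait dimension.

## Benchmark conditions and problem sizes

The validation suite (`tests/test_acceptance.py`, `scripts/acceptance.py`)
uses 200 simulated regions at n = 5,000 individuals, J = 500 SNPs, R = 5
traits, AR(1) LD 0.9, and target max PVE 5% — an inflated effect size so
that credible sets are plentiful enough to measure coverage with 200
replicates; the 0.05% default is kept for the PVE-calibration check
itself, measured at n = 50,000. Each region is fitted end-to-end through
the summary-data pipeline: z-scores and in-sample LD, V estimated from the
region's own near-null z-scores (identity fallback if fewer than two
survive the filter), canonical prior, L = 10, 95% credible sets, purity
filter 0.5. Passing these checks demonstrates internal consistency of the
whole pipeline under the model's own assumptions at realistic signal
strengths; it does not demonstrate robustness to out-of-sample LD,
allele-frequency artifacts, or model misspecification on real genotypes.

## Known limitations

- V is fixed during fitting; there is no residual-covariance update inside
  the multivariate loop, and no missing-data handling.
- Mixture weights ω are fixed at prior-construction time, not re-estimated
  within IBSS.
- The EM scale update's zero state is absorbing within a run.
- Likelihoods are Gaussian; case-control traits are out of scope.
- No allele-flip detection in the summary-data pathway (allele columns are
  not part of the input format); LD diagnostics are limited to PSD repair.
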