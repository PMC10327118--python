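# mvsusie

Multi-trait genetic fine-mapping with the multivariate Sum of Single
Effects (mvSuSiE) model.

GWAS associations rarely identify causal variants directly: linkage
disequilibrium (LD) spreads each signal over many nearby SNPs.
Fine-mapping resolves this statistically, and doing it *jointly across
related traits* borrows strength whenever causal variants affect several
traits at once. This package is for statistical geneticists who want to
fine-map a region for R traits from any of:

- individual-level data (genotype matrix X, trait matrix Y),
- sufficient statistics (X'X, X'Y, N), or
- standard GWAS summary statistics (a J x R matrix of z-scores, an LD
  correlation matrix, and the sample size).

## Model

The regression is matrix-normal, `Y = X B + E`, with the R x R residual
covariance V treated as known (estimated beforehand from null z-scores).
The coefficient matrix is a sum of L "single effects",

    B = Σ_l γ^(l) (b^(l))',     γ^(l) ~ Multinom(1, π),

so each single effect places a multivariate coefficient b ∈ R^R on exactly
one SNP. Effect sharing across traits enters through a
mixture-of-multivariate-normals prior,

    b^(l) ~ Σ_k ω_k N(0, σ²_{0l} U_k),

whose covariance patterns U_k encode sharing shapes (independent, equal,
trait-specific, heterogeneous, or patterns learned from the data by
Extreme Deconvolution). The per-effect scales σ²_{0l} are estimated by EM;
scales driven to zero prune unneeded effects (automatic relevance
determination), so L only needs to be an upper bound.

Fitting is Iterative Bayesian Stepwise Selection (IBSS): coordinate ascent
on a variational bound in which each single-effect update is an exact
Bayesian computation on residualized data. Because the likelihood depends
on the data only through X'X and X'Y, the same algorithm runs from
sufficient statistics (IBSS-ss), and — since for standardized data
`X'X = N R̂` and `X'Y = √N Z̃` with Z̃ the adjusted z-scores
`z̃ = z √(N/(N+z²))` — from GWAS summary data (mvSuSiE-RSS).

Reported posterior summaries:

- **PIP** per SNP: probability of a non-zero effect on at least one trait,
  `PIP_j = 1 − Π_l (1 − α_j^(l))`;
- **credible sets (CS)**: per single effect, the smallest set of SNPs with
  posterior mass ≥ ρ (default 0.95), filtered at purity ≥ 0.5 (purity =
  minimum |LD correlation| among members);
- **lfsr** (local false sign rate) per SNP/trait and its α-weighted
  average per CS/trait: a CS is "significant for trait r" when the average
  lfsr is below 0.01.

## Worked example

Simulate a 500-SNP region for 5 traits (5,000 individuals, AR(1)-style LD,
strongest trait's PVE 5%) and fine-map it from the summary statistics:

```sh
mvsusie simulate --n 5000 --n-snps 500 --n-traits 5 \
    --target-max-pve 0.05 --seed 1 --out-prefix region
mvsusie fit-rss --z region.z.tsv --ld region.ld.tsv --n 5000 \
    --out-prefix fit
```

The simulated truth (`region.truth.json`) has one causal SNP, index 54
(label `snp55`). The fit reports one credible set (`fit.cs.tsv`):

```
cs    effect  members  mass  purity  sentinel  avg_lfsr_trait1  ...  significant_traits
CS1   0       snp55    1.0   1.0     snp55     9.1e-40               trait1,trait3
```

and `fit.pips.tsv` gives `snp55` a PIP of 1.0 with every other SNP at ~0:
the causal variant is recovered exactly, and the per-trait average lfsr
says the sign of its effect is only trustworthy for traits 1 and 3
(avg lfsr 9e-40 and 1e-6; the other traits are at 0.04–0.36, above the
0.01 threshold).

The same analysis from a library session:

```python
import mvsusie as mv
truth, css, fit, pip = mv.simulate_region_and_finemap(seed=1)
```

Other subcommands: `fit` (individual-level TSVs), `fit-ss` (sufficient
statistics), `estimate-resid-cov` (residual correlation from pooled null
z-scores), `estimate-prior` (data-driven prior via Extreme Deconvolution),
and `regions` (merge per-trait association hits into disjoint fine-mapping
regions, BED output).

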