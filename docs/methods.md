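# Methods

## Model

A gene × cell count matrix is treated as n iid draws of an m-dimensional
count vector X. The joint CDF is factorized by Sklar's theorem into
per-gene margins Fᵢ and a copula C. Margins are always empirical: support
= sorted unique observed counts, CDF by counting. This is deliberate — the
package's purpose is to compare copula estimators, and a parametric margin
that fits poorly would contaminate every copula it is paired with. The
cost is that synthetic counts can only take values observed in training
data; for n in the hundreds or more this truncation is negligible.

Because the margins are discrete, the copula is not identifiable (any
copula agreeing on the closure of ran F₁ × … × ran F_m yields the same
joint law), but parameters within a fixed family are; all estimators here
target family parameters, not the copula function itself.

### Copula-scale representations of counts

Every observation x of a gene is represented on the copula scale by the
rectangle (F(x−), F(x)]. Three derived quantities are used:

* midpoints (F(x−)+F(x))/2 — deterministic, used by the "sample" Gaussian
  estimator through normal scores;
* the rectangle endpoints themselves — used by likelihoods that integrate
  the latent uniform over the rectangle (ML Gaussian, discrete vine);
* the distributional transform U = F(x−) + V (F(x) − F(x−)),
  V ~ Uniform(0,1) iid — "jittering". U is exactly Uniform(0,1) and
  exactly invertible back to x given the margin table.

All copula-scale values carry an n/(n+1) rescale so that Φ⁻¹ and t⁻¹
stay finite. Ties between equal counts are broken only by the independent
V draws of the jitter; no mid-rank splitting is used anywhere else.

### Estimators

* **Gaussian (sample)**: normal scores z = Φ⁻¹(midpoints), sample
  correlation, nearest-correlation repair. A constant gene has no rank
  information; its correlations are set to 0 with a logged warning.
* **Gaussian (jittered)**: same with z = Φ⁻¹(U) for one seeded jitter
  draw.
* **Gaussian (ML)**: pairwise composite likelihood. For each gene pair,
  ρ̂ maximizes Σ_cells log P(rect) where P(rect) is the bivariate-normal
  rectangle probability at the pseudo-observation endpoints; rectangles
  are aggregated over unique count pairs for speed, and the bivariate
  normal CDF is evaluated by Owen's-T reduction (vectorized, checked
  against numerical integration in the tests). The assembled matrix is
  repaired by nearest_correlation. The full m-dimensional discrete
  likelihood would require m-dimensional rectangle probabilities whose
  cost grows exponentially; the pairwise surrogate preserves per-pair ML
  semantics at tractable cost. Failed pair optimizations fall back to the
  sample estimate, logged.
* **t (two-stage)**: stage 1 estimates R entrywise by Kendall-τ
  inversion R = sin(πτ/2) on one jittered draw, with nearest-correlation
  repair; stage 2 profiles the jittered-data t-copula log-likelihood over
  ν ∈ [1, 100] by bounded scalar search (tolerance 1e-3) with R fixed.
* **Vine**: Dissmann's sequential construction. Each tree is a maximum
  spanning tree on |Kendall τ| of the current conditional pseudo-data
  (Kruskal, with deterministic lexicographic tie-breaks), restricted by
  the proximity condition. Each edge first runs an asymptotic Kendall-τ
  independence test (α = 0.05 by default; non-significant edges become
  independence pairs, keeping vines sparse), then fits every candidate
  family by scalar ML and keeps the AIC minimizer. Families: gaussian,
  clayton, gumbel, frank; clayton/gumbel additionally try the rotations
  consistent with the sign of τ (0/180 for positive, 90/270 for
  negative). The t pair family is excluded because the discrete
  rectangle likelihood needs a closed-form pair CDF. In discrete mode
  every conditional margin carries its (minus, plus) endpoint pair;
  parameters are fit by the four-point rectangle likelihood
  C(u⁺,v⁺) − C(u⁻,v⁺) − C(u⁺,v⁻) + C(u⁻,v⁻), and conditioning on a
  discrete variable uses the difference quotient of the pair CDF across
  the conditioning rectangle. The simplified assumption (conditional
  pair-copula parameters do not depend on conditioning values) is used
  throughout. Truncated vines keep the full tree structure but carry
  independence pairs beyond the truncation level.

### Sampling

Gaussian and t copulas sample via Cholesky (eigendecomposition fallback
for near-singular R). Vines sample by inverse Rosenblatt: variables are
drawn in the diagonal order of the R-vine matrix built from the fitted
trees, and each fresh uniform is pushed through the column's inverse
h-functions; intermediate conditional CDFs are cached keyed by their
(variable, conditioning-set) meaning, which makes a structural
inconsistency a loud KeyError instead of a silent wrong sample. The
gumbel h-function has no closed-form inverse and is inverted by 60-step
bisection (error < 1e-15); all other inverses are closed-form.

Joint-model sampling maps each copula coordinate through the generalized
inverse of the gene's empirical CDF, so per-gene count frequencies are
preserved by construction (verified by a chi-square battery).

## Evaluation

Association matrices support six measures. Choices where a convention was
needed: biweight midcorrelation uses tuning constant 9 with Pearson
fallback for zero-MAD genes (per-gene, as in WGCNA's "individual"
fallback); mutual information uses equal-frequency binning with
B = ⌈n^(1/3)⌉ bins and the Miller–Madow correction, reported in nats with
self-information on the diagonal; distance correlation is the classical
double-centered O(n²) estimator with cells subsampled (seeded) to 2000
when larger, logged when applied. Constant genes yield 0 entries, never
NaN. The Frobenius error is the full-matrix Frobenius norm of the
difference, diagonal included.

The embedding comparison projects synthetic cells into the 2-PC space of
the reference (test) half — loadings and centering come from the
reference only and are never refit. The embedding input is log1p of raw
counts without library-size scaling, so synthetic cells with zero totals
remain projectable. The Fasano–Franceschini statistic is the maximum over
sample-point-anchored orthant quadrants of the occupancy-fraction
difference, maximized separately with each sample's points as origins
and averaged; p-values come from label permutation with add-one
smoothing, p = (1 + #{D_perm ≥ D_obs}) / (1 + n_perm), with 100
permutations by default (minimum attainable p = 1/101). Dimensions 2 and
3 are supported.

The benchmark protocol: equal half-splits of cells (no stratification —
the intended inputs are single-cell-type, single-donor datasets, so
there is no covariate to stratify on), the same splits for every family;
per split each family is fit on train, 20 synthetic replicates the size
of the test half are drawn, each replicate is scored (Frobenius per
measure, FF p-value in test PC space), and statistics are averaged first
over replicates within a split and then over splits. Family comparisons
use the Wilcoxon signed-rank test on per-dataset paired means ("paired
Wilcoxon"), Benjamini–Hochberg adjustment across pairs, and the
matched-pairs rank-biserial correlation (T⁺ − T⁻)/(T⁺ + T⁻) as effect
size. A `module_hook` callable receiving (train, test, synthetic) count
matrices lets an external network-analysis pipeline consume the same
triples; no module-preservation analysis is implemented here.

## Ground-truth generator

`generate_truth` draws U from a known copula (independence; Gaussian or
t with exchangeable, AR1 or block correlation; or a small vine — default
d = 3 with a clayton(θ=2) edge, a gaussian(ρ=0.5) edge and a conditional
independence edge) and maps coordinates through zero-inflated negative
binomial quantile functions. Defaults are mu = 5, theta = 2, pi = 0.1
(variance mu + mu²/theta; ≈18% zeros, ~30 distinct counts per gene at
n = 5000) — the profile of a moderately expressed highly-variable gene,
the gene class these models are meant to be fit on. A sparse preset
(mu = 0.5, pi = 0.9, ≥85% zeros) emulates unfiltered genes. What the
generator does not emulate: batch effects, cell-type mixtures, varying
library sizes, and ambient contamination; passing tests therefore show
estimator correctness under the stated model, not robustness to those
real-data artifacts.

Recovery tests for the Gaussian estimators use the default margins. The
two-stage t fit is consistent only as discretization vanishes: with the
default margins its ν̂ is biased upward (≈8.3 for a true ν = 5 at
n = 5000) because jittering dilutes tail co-movements across the zero
atom. Its recovery test therefore uses a near-continuous preset
(mu = 10, theta = 3, pi = 0.05; ~50 distinct values per gene), where
ν̂ ≈ 5.7–6.7; the attenuation under sparser margins is a known
limitation of jittered likelihoods, and is the same effect that makes
jittered estimators less accurate than count-based ones on real data.

## Numerical choices

* Correlation repair: alternating projections (statsmodels
  `corr_nearest`) with eigenvalue floor 1e-8 and unit-diagonal
  renormalization; inputs already valid pass through unchanged.
* Copula-scale values are clipped to [1e-12, 1 − 1e-12] before quantile
  transforms; clayton/gumbel power transforms cap exponents at 700 to
  avoid overflow at extreme θ and u.
* Optimizer bounds: gaussian ρ ∈ (−0.999, 0.999), clayton θ ∈ (1e-3, 28],
  gumbel θ ∈ (1, 17], frank θ ∈ [−35, 35] excluding (−0.01, 0.01) (the
  removable singularity at 0 is covered by the independence pre-test).
* All stochastic steps (splits, jitter, sampling, permutations,
  subsampling) take explicit seeds; identical configuration and seed
  reproduce the full record stream bit-for-bit.
* HVG selection fits a running-median variance trend over a window of
  one third of genes (so a small block of genuinely hypervariable genes
  cannot define its own trend) on log1p counts-per-10k (scale 1e4,
  natural log); both the scale and the trend window are conventions, not
  claims about an optimal HVG model, and gene selection only fixes the
  modeling universe.

## Problem sizes

Default study sizes used by the test suite and `scripts/acceptance.py`:
parameter recovery at m = 5, n = 5000; vine recovery at d = 3, n = 4000;
calibration studies with 100–200 seeded replicates; benchmark-ordering
studies at m ∈ {3, 5}, n ∈ {1200, 1500} with 5–10 seeds. These sizes
put Monte-Carlo error comfortably inside the asserted tolerance bands
while keeping a full run in minutes on one CPU.

## Known limitations

* The ML Gaussian is a pairwise composite likelihood, not the full
  m-dimensional discrete MLE; the two coincide asymptotically for
  exchangeable-like dependence but can differ under strong conditional
  structure.
* Vine fitting cost grows with d²·n; the implementation is intended for
  the 10–100 gene regime, not thousands of genes.
* The FF embedding comparison uses 2 or 3 PCs only.
* Mutual information via fixed equal-frequency binning is a coarse
  estimator; it is used as a comparative score, not an absolute one.
* Synthetic counts never leave the training support of each gene.
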