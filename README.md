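# coexcopula

Copula models of gene coexpression for single-cell RNA-seq count matrices.

Single-cell RNA-seq data are integer transcript counts for m genes across n
cells — sparse, overdispersed and often zero-inflated. Modeling how genes
co-vary (not just how each gene is distributed on its own) matters for any
method that simulates realistic synthetic cells, tests coexpression, or
performs in-silico perturbation with a ground truth. By Sklar's theorem, any
joint distribution H of the count vector X = (X₁, …, X_m) factors as

    H(x₁, …, x_m) = C(F₁(x₁), …, F_m(x_m)),

where Fᵢ is the marginal CDF of gene i and C is a copula — a multivariate CDF
with Uniform(0,1) margins that carries all of the dependence. This package
keeps the margins empirical (per-gene step CDFs, so margin misspecification
never contaminates the dependence model) and provides six copula models of C:

| family | parameters | estimator |
| --- | --- | --- |
| independence | none | — |
| Gaussian | correlation matrix R | normal scores of pseudo-observation midpoints |
| jittered Gaussian | R | normal scores of distributional-transform draws |
| ML Gaussian | R | pairwise composite ML on bivariate-normal rectangle probabilities |
| t | R, degrees of freedom ν | Kendall-τ inversion R = sin(πτ/2), then profile ML for ν ∈ [1, 100] |
| vine (on counts or jittered) | pair copulas on a tree hierarchy | Dissmann greedy structure + AIC family selection (gaussian/clayton/gumbel/frank + rotations) |

Because counts are discrete, each observation's copula-scale value is only
known to lie in the rectangle (F(x−), F(x)]. Estimators either work with the
rectangle endpoints directly (ML Gaussian, discrete vine) or make the margins
continuous by the distributional transform U = F(x−) + V·(F(x) − F(x−)),
V ~ Uniform(0,1) ("jittering"), which is exactly uniform and exactly
invertible back to the counts.

Fitted joint models are sampled by drawing U from the copula (inverse
Rosenblatt for vines) and pushing each coordinate through the generalized
inverse of its empirical margin, so synthetic counts reproduce the training
margins by construction. An evaluation suite scores how well each family
reproduces held-out coexpression: gene–gene association matrices under six
measures (Pearson, Spearman, Kendall, mutual information, biweight
midcorrelation, distance correlation) compared by Frobenius error
‖Ms − Mr‖_F, plus a Fasano–Franceschini permutation test (a multivariate
Kolmogorov–Smirnov-type two-sample test) on fixed-reference 2-PC embeddings.
A bundled generator produces ground-truth data — zero-inflated negative
binomial margins coupled by a known copula — so every estimator is testable
against a known answer.

## Worked example

```python
import numpy as np
from coexcopula import (generate_truth, fit_joint, sample_joint,
                        assoc_matrix, frobenius_error)

truth = generate_truth(m=5, n=2000,
                       dependence_spec={"kind": "exchangeable", "rho": 0.5},
                       copula_family="gaussian", rng_seed=1)
jm = fit_joint(truth.counts, "gaussian")
print(np.round(jm.copula.R.values, 3))

syn = sample_joint(jm, 2000, rng_seed=2)
ref = assoc_matrix(truth.counts, "spearman")
err_g = frobenius_error(assoc_matrix(syn, "spearman"), ref)
syn0 = sample_joint(fit_joint(truth.counts, "independence"), 2000, rng_seed=2)
err_0 = frobenius_error(assoc_matrix(syn0, "spearman"), ref)
print(f"Frobenius error (spearman): gaussian={err_g:.3f} independence={err_0:.3f}")
```

prints

```
[[1.    0.471 0.467 0.446 0.467]
 [0.471 1.    0.453 0.447 0.498]
 [0.467 0.453 1.    0.473 0.469]
 [0.446 0.447 0.473 1.    0.467]
 [0.467 0.498 0.469 0.467 1.   ]]
Frobenius error (spearman): gaussian=0.049 independence=2.005
```

All ten true pairwise correlations are 0.5; the sample estimator recovers
them to within ±0.06 from 2000 cells of discrete, zero-inflated counts. The
Frobenius errors show what the dependence model buys: synthetic data from the
fitted Gaussian copula reproduce the held-out Spearman matrix almost exactly,
while margin-identical synthetic data with independent genes miss it by two
orders of magnitude more.

The same workflow is available from the shell:

```sh
coexcopula generate --genes 10 --cells 2000 --family gaussian --rho 0.5 \
    --out truth.mtx --truth-out truth.json --seed 1
coexcopula ingest --counts truth.mtx --genes truth.genes.tsv \
    --barcodes truth.barcodes.tsv --min-expr-frac 0.02 --out staged.csv
coexcopula fit --counts staged.csv --family vine --out model.json --seed 2
coexcopula simulate --model model.json --cells 2000 --out synthetic.csv --seed 3
coexcopula benchmark --counts staged.csv \
    --families independence,gaussian,vine --splits 5 --replicates 20 \
    --measures all --out records.csv --seed 4
```

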