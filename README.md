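# survmoe

Bayesian **infinite mixture-of-experts survival regression**: a truncated
Dirichlet-process mixture in which every mixture component ("expert")
couples a Normal density over the covariates with a Weibull
proportional-hazards regression whose coefficients carry a Bayesian
group-lasso sparsity prior.  The model simultaneously

* partitions a patient cohort into an *unknown* number of survival
  sub-groups,
* fits each sub-group its own baseline hazard (Weibull shape and scale),
  and
* selects, per sub-group, the covariates and higher-order interactions
  (pairs, triplets) that actually drive the hazard.

It is aimed at right-censored time-to-event cohorts with categorical or
continuous covariates — e.g. protein-marker intensities from tissue
microarrays — where both the sub-group structure and the per-group
compound markers are unknown.

## Model

For subject *i* with covariates *x* and time *t* (censoring indicator
δ), each expert *c* has parameters φ_c = (μ_c, σ²_xc, α_c, λ_c, β_c, …):

* covariates: x ~ N(μ_c, diag σ²_xc) with a Normal-Inv-χ² conjugate prior;
* hazard: h(t|x) = (α/λ)(t/λ)^{α−1} exp(η), a Weibull baseline with
  multiplicative covariate effect (proportional hazards);
* random link: η = x̃ᵀβ + ε, ε ~ N(0, σ²), where x̃ is the grouped
  design vector (polynomial contrasts for ordered categorical variables,
  products for interactions up to second order);
* sparsity: β carries the group-lasso hierarchy
  λ_g ~ Gamma((p_g+1)/2, ρ²/2), β_g|λ_g ~ N(0, σ²λ_g I), whose marginal
  is a multivariate Laplacian per group — whole interaction groups are
  shrunk to zero together;
* mixture: component indicators follow a Dirichlet process truncated at
  M components (Dirichlet-Multinomial allocation, weights
  Dirichlet(α_DP/M + counts)).

Inference is blocked Gibbs sampling: per-expert conjugate updates for the
covariate density, the Weibull scale (Inverse-Gamma on v = λ^α), the
shape (grid sampling of its analytically scale-integrated marginal), a
Laplace-approximation draw for each log-concave η_i conditional, the
four group-lasso conditionals, then assignments and weights.

## Worked example

The frozen two-cluster simulation benchmark: n = 150 subjects, half from
a Weibull(5, 5) cluster (covariate means 0.3), half from a Weibull(1, 1)
cluster (means 0.7), seven covariates expanded to second order (63
interaction terms), seven active terms per cluster with coefficient 3.

```python
import numpy as np
import survmoe as sm
from survmoe import benchmark as bm

fit = bm.fit_benchmark(seed=1, n_iter=8000, burn_in=2000)
recovery = fit.recovery()
print(f"occupied clusters: {recovery.n_occupied}")
print(f"adjusted Rand index vs truth: {recovery.ari:.2f}")
for cluster, expert in sorted(recovery.matched_expert.items()):
    draws = fit.chain.shape[:, expert]
    lo, hi = np.quantile(draws, [0.025, 0.975])
    print(f"cluster {cluster}: Weibull shape median "
          f"{np.median(draws):.2f} (95% CI {lo:.2f}-{hi:.2f})")
summary = sm.term_significance(fit.chain, recovery.matched_expert[1], q=0.8)
top = summary.table.sort_values("sign_consistency", ascending=False).head(4)
print(top[["sign_consistency", "ci_lo", "ci_hi", "significant"]])
```

prints

```
occupied clusters: 2
adjusted Rand index vs truth: 1.00
cluster 0: Weibull shape median 5.37 (95% CI 4.31-6.61)
cluster 1: Weibull shape median 1.05 (95% CI 0.72-1.23)
          sign_consistency     ci_lo     ci_hi  significant
term
x2:x6:x7          0.970167  0.047337  0.384848         True
x6:x7             0.801167 -0.026090  0.342573        False
x3:x5:x7          0.794000 -0.191067  0.019215        False
x2:x4:x7          0.769333 -0.028989  0.159104        False
```

Both generating clusters are found (exactly 2 of the M = 10 truncation
slots are occupied, perfect agreement with the true labels), the
matched posterior shape medians bracket the generating values 5 and 1,
and the planted triplet interaction x2:x6:x7 is the most sign-consistent
term of its cluster — 97% of its posterior draws are positive, so its
central 80% interval excludes zero.

## Command line

```bash
survmoe simulate --preset benchmark --seed 1 --out cohort.csv
survmoe fit --data cohort.csv --config fit.yaml --out-dir chain/
survmoe report --chain chain/ --data cohort.csv --out-dir report/
survmoe compare --chain-moe chain/ --chain-single single/ \
    --test test.csv --train cohort.csv --config fit.yaml --out compare.json
```

`fit.yaml` declares the time/status columns, each covariate's factor
spec, the interaction order and the sampler settings; all outputs are
plain CSV/JSON.

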