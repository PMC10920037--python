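# psytraj

Deep-embedding clustering of multi-informant psychopathology trajectories,
with prediction-strength model selection and multiply-imputed multinomial
regression of baseline predictors.

## The problem

Adolescent mental-health cohorts follow the same children for years,
collecting many symptom scales from two informants (the adolescents
themselves and their caregivers) at a handful of waves, with scales that
appear and disappear across waves and plenty of missing responses.  A
central question is whether a small number of *trajectory classes* —
e.g. an unaffected majority, a persistently internalizing group, a group
whose self-reported distress their caregivers do not see — organizes this
high-dimensional longitudinal data, and which baseline characteristics
predict membership in each class.

`psytraj` implements that analysis end to end for methodologists and
simulation studies:

* a **synthetic cohort generator** producing four-wave, 14-assessment,
  two-informant cohorts with known latent classes, known
  covariate-to-class log-odds, realistic bounded/skewed item responses,
  structurally missing waves and MCAR missingness;
* **preprocessing**: iterative random-forest item imputation
  (100-tree forests, stop when the normalized change rises), unrounded
  scale scoring, pooled z-standardization into a masked
  participant × wave × assessment tensor;
* **clustering** with a recurrent variational deep-embedding model: an
  LSTM autoencoder whose L-dimensional latent has a K-component Gaussian
  mixture prior, trained on masked reconstruction + mixture-KL latent
  loss while *learning* the imputation values for unobserved inputs;
* **model selection**: repeated 2-fold prediction strength over candidate
  K, and reconstruction-loss grid search for hyperparameters;
* **predictor analysis**: ANOVA/chi-square screening, chained-equation
  multiple imputation, baseline-category multinomial logistic regression,
  Rubin-rule pooling, Nagelkerke R² and (generalized) VIF.

## The model

For participant *i* with trajectory x ∈ R^{T×D} (T = 4 waves, D = 14
z-scored assessments) and observation mask m:

* inputs are completed as x̃ = m⊙x + (1−m)⊙B with learned imputation
  values B;
* an LSTM encoder gives q(z|x) = N(μ̃, diag σ̃²), z ∈ R^L;
* the prior is p(z) = Σ_c π_c N(z; μ_c, diag σ²_c), c = 1..K;
* the loss is the masked reconstruction error Σ m⊙(x − x̂)² / Σ m plus
  the latent term Σ_c γ_c KL(q ‖ N(μ_c, σ²_c)) + Σ_c γ_c log(γ_c/π_c),
  with responsibilities γ_c ∝ π_c N(z; μ_c, diag σ²_c);
* clustering is argmax_c γ_c at z = μ̃.

K is chosen by prediction strength: the minimum over test clusters of the
fraction of within-cluster pairs that a model trained on the *other* half
of the data co-assigns, averaged over repeated random halvings; the
largest K clearing a 0.8 threshold wins.

Cluster membership is then regressed on baseline covariates with a
multinomial logit (reference = the flat-low class); m imputed datasets are
combined by Rubin's rules: Q̄ = mean coefficient, T = W + (1+1/m)B,
OR = exp(Q̄) with t-based CIs.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from psytraj import (low_noise_cohort_spec, generate_cohort, score_table,
                     standardize, VaderConfig, fit, assign, cluster_shares)

spec = low_noise_cohort_spec(500, seed=100)          # 5 planted classes
cohort = generate_cohort(spec)
tensor = standardize(score_table(cohort.item_table, spec.assessments),
                     spec.assessments)               # (500, 4, 14) masked
model, log = fit(tensor, VaderConfig(k=5, latent_dim=8, epochs=100, seed=0))
labels = assign(model, tensor).labels
print(cluster_shares(labels))
print("ARI vs truth:",
      round(adjusted_rand_score(cohort.true_labels.to_numpy(), labels), 3))
```

Output:

```
   cluster  count  share_pct
0        0    299       59.8
1        2     75       15.0
2        3     52       10.4
3        1     49        9.8
4        4     25        5.0
ARI vs truth: 0.994
```

The five recovered clusters match the planted shares (≈ 60/16/10/10/4 %)
and the adjusted Rand index against the generator's true labels is 0.994:
all but a few boundary participants are co-clustered exactly as planted.

The same workflow is available from a shell:

```bash
psytraj simulate --n 500 --seed 1 --out runs/cohort
psytraj run --n 500 --seed 1 --out runs/full     # all stages end to end
```

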