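# lsirm

Bayesian latent space item response modelling for comparing two
informants' reports on the same questionnaire.

## The problem

Parent-report and self-report versions of the same symptom checklist
(e.g. the CBCL and the YSR) routinely disagree, and classical agreement
measures — syndrome-level Pearson correlations, item-level Cohen's κ,
Jaccard similarity of item pairs — treat items and respondents as
independent, so they cannot say *where* the disagreement lives: in item
easiness, in item–item dependency, or in how respondents relate to
syndromes.

The latent space item response model (LSIRM) embeds items and
respondents in a shared d-dimensional *interaction map*.  For respondent
k and item i with binary response y_ki,

    logit P(y_ki = 1) = β_i + θ_k − ‖w_i − z_k‖,

where β_i is item easiness, θ_k the respondent trait, and w_i, z_k are
latent positions; short distances mean strong dependency.  Fitting one
LSIRM per informant and matching the two maps turns "the informants
disagree" into concrete, testable statements: which items are easier for
one informant, which item pairs change their dependency, how syndrome
geometry differs, and which respondents would be profiled differently.

The package provides:

* a Metropolis–Hastings-within-Gibbs sampler with conjugate updates for
  the trait variance and Bayesian data augmentation for missing
  responses, behind a scikit-learn-style estimator (`LSIRM`);
* Procrustes post-processing for latent-position identifiability within
  a chain and Procrustes matching of two fitted maps;
* discrepancy statistics: item-easiness comparison with outlier
  flagging, posterior distance-distribution overlap R (pairs flagged at
  R ≤ 0.05), KL divergence, KS tests, syndrome-centroid cosine
  similarity, respondent–syndrome distance profiles with K-means
  clustering;
* classical baselines (correlations, κ, Jaccard differences) and
  goodness-of-fit metrics;
* a synthetic paired-informant data generator with controllable,
  ground-truthed discrepancy, so the whole pipeline is testable without
  access-restricted clinical data;
* a CLI (`lsirm simulate / fit / compare / baselines / gof / run`).

## Worked example

```python
from lsirm import (LSIRM, beta_compare, match_maps, overlap_heatmap,
                   positive_rate, preset, simulate_paired)
from lsirm.assessment import confusion, gof_metrics

# paired 150 x 32 dataset: 4 items easier for the self-informant,
# one 3-item cluster displaced in the self-informant's map
paired, truth = simulate_paired(preset("small", seed=7))
print(f"positive rate (parent): {positive_rate(paired.a):.3f}")
print(f"positive rate (self):   {positive_rate(paired.b):.3f}")

fit_a = LSIRM(n_iterations=6000, burn_in=1500, thin=3, random_state=1).fit(paired.a)
fit_b = LSIRM(n_iterations=6000, burn_in=1500, thin=3, random_state=2).fit(paired.b)
matched_b = match_maps(fit_a.fitted_model_, fit_b.fitted_model_)

bc = beta_compare(fit_a.fitted_model_, matched_b)
print(f"easiness correlation r = {bc.pearson_r:.2f}")
print(f"flagged items: {bc.flagged_items}")
print(f"injected shifted items: {truth.shifted_items}")

heat = overlap_heatmap(fit_a.fitted_model_, matched_b, max_draws=500)
print(f"pairs flagged at R <= 0.05: {100 * heat.flagged_proportion:.1f}%")

m = gof_metrics(confusion(fit_a.fitted_model_, paired.a))
print(f"GOF parent fit: sens {m.sensitivity:.2f}, spec {m.specificity:.2f}, acc {m.overall_accuracy:.2f}")
```

Output (about a minute on one core):

```
positive rate (parent): 0.265
positive rate (self):   0.432
easiness correlation r = 0.79
flagged items: ['item019', 'item025', 'item026', 'item027', 'item028']
injected shifted items: ['item025', 'item026', 'item027', 'item028']
pairs flagged at R <= 0.05: 0.0%
GOF parent fit: sens 0.55, spec 0.91, acc 0.82
```

Reading it: the generator calibrated the two instruments to the target
positive-response rates (0.27 parent, 0.43 self).  After independent
fits and map matching, the easiness comparison recovers all four items
that were made easier for the self-informant (plus one chance flag), and
the overall β correlation of 0.79 reflects that injected discrepancy.
At this small size no item pair crosses the conservative R ≤ 0.05
distributional-difference threshold — position posteriors are wide at
N = 150 — while the larger experiments in `tests/test_acceptance.py`
show the flagged pairs concentrating on the displaced cluster.  The
goodness-of-fit row is the usual in-sample classification summary of a
fitted LSIRM.

The same workflow runs end-to-end from one config:

```sh
lsirm run --config run.yaml     # simulate/ingest -> fit x2 -> match -> reports
```

writing the β table, overlap-R matrix, ranked discrepant-pair tables,
cosine matrices, cluster assignments, GOF and baseline tables plus a
manifest under the configured output directory.

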