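# Methods

## Model

`lsirm` implements a Bayesian latent space item response model (LSIRM)
for binary respondent × item data.  For respondent *k* = 1…N and item
*i* = 1…P,

    logit P(y_ki = 1) = β_i + θ_k − ‖w_i − z_k‖,

with item easiness β_i, respondent latent trait θ_k, and positions
w_i, z_k ∈ R^d in a shared latent space (the *interaction map*; d = 2 by
default).  The distance weight is fixed at one.  The distance term relaxes
the Rasch model's conditional-independence and homogeneity assumptions:
items close to each other in the map are endorsed by the same respondents
beyond what β and θ explain, and the triangle inequality makes this
dependency transitive.

Priors:

    β_i ~ N(0, τ_β²),   θ_k ~ N(0, σ²),   σ² ~ Inv-Gamma(a_σ, b_σ),
    w_i ~ N_d(0, I),    z_k ~ N_d(0, I).

Defaults τ_β² = 4, a_σ = b_σ = 1 are weakly informative on the logit
scale; all are configurable (`Hyperparameters`).

## Estimation

Metropolis–Hastings-within-Gibbs (`lsirm.sampler`):

* β, θ, rows of W and rows of Z are updated by componentwise Gaussian
  random walks.  Each block's full conditional factorizes over its
  components (the Bernoulli likelihood factorizes over cells and each
  cell involves one β_i, one θ_k, one w_i and one z_k), so all
  components of a block are proposed and accepted/rejected in parallel.
* σ² is drawn exactly from its conjugate full conditional
  Inv-Gamma(a_σ + N/2, b_σ + Σθ_k²/2).
* Proposal scales (one per block) adapt during burn-in by Robbins–Monro
  toward an acceptance rate of 0.35 (inside the usual 0.23–0.44 band for
  componentwise random walks) with a decaying step, and are frozen at the
  end of burn-in, so the retained chain is a valid time-homogeneous
  Markov chain.
* Default schedule: 30 000 iterations, 5 000 burn-in, thinning 5 → 5 000
  retained draws.  `LSIRM(n_chains=k)` runs k independent chains from
  distinct seeds, Procrustes-aligns them into the first chain's MAP frame
  and pools the draws; pooled chains cover minor posterior modes (e.g.
  near-symmetric placements of a single item) that one chain of the same
  total length can miss.  The scaled-down experiments in the tests and
  the acceptance script use 8 000/2 000/4 (recovery, one chain) and two
  pooled 8 000/2 000/4 chains (cross-informant comparisons) at
  N = 300–400, P = 60; these sizes were chosen so a full run completes in
  minutes on one core while leaving the Monte-Carlo error of posterior
  means well below the posterior standard deviations.
* Initialization is deterministic given the seed: β at the clipped logit
  of the observed item rates, θ = 0, positions from N(0, 0.1·I), σ² = 1.
  Identical seeds give bit-identical chains.
* The stored log posterior keeps all normalizing constants (including the
  σ²-dependent ones), so the maximum-a-posteriori (MAP) draw is well
  defined across draws; ties break to the earliest retained draw.

### Missing responses

Missingness is assumed missing-at-random and handled by Bayesian data
augmentation: at the start of every sweep each missing cell is redrawn
as Bernoulli at the current parameters and then conditioned on like
observed data.  Imputed values are stored per retained draw.  A
partially observed matrix with an entirely missing row or column is
rejected (those parameters would be sampled from their prior while
silently degrading neighbours' updates — drop the row/column instead).
An *entirely* missing matrix is accepted deliberately: the augmented
target then marginalizes exactly to the prior, which the test suite
uses as a distributional correctness check of the whole sampler.

## Identifiability post-processing

The likelihood depends on positions only through distances, so the
posterior is invariant to rotation, reflection and translation of the
configuration.  Two Procrustes steps (`lsirm.alignment`) remove this:

1. **Within a chain** every retained draw's stacked (W; Z) configuration
   is mapped by the rigid motion minimizing the squared distance to the
   MAP draw's configuration.
2. **Across instruments** the two fitted maps are matched by a rigid
   motion estimated on posterior-mean *item* positions only — items are
   the objects shared verbatim between instruments, while respondents may
   genuinely sit elsewhere — and broadcast to respondent positions and to
   every retained draw.

Scale is never estimated: a scale factor would change distances and hence
the model.  All distance-based statistics are invariant to both steps by
construction, which the tests verify to 1e-10.

## Discrepancy statistics

Given matched fits for two informants (`lsirm.discrepancy`):

* **Item easiness comparison.**  Pearson correlation of the posterior-mean
  β vectors and an OLS trend line.  Off-trend items are flagged when the
  residual from a Huber robust regression exceeds 2.5 median-absolute-
  deviation units.  A plain studentized-OLS cut was evaluated first and
  rejected: with ~13 % of items shifted by 1.5 logits (the phenomenon this
  statistic exists to find), the shifted items inflate the OLS residual
  scale enough to mask themselves (1/8 found in a pilot); the robust
  scale is set by the on-trend majority and finds 6–8/8.  Externally
  studentized OLS residuals are still reported for reference.
* **Item-pair dependency.**  For each item pair the posterior distribution
  of ‖w_i − w_j‖ per instrument (one sample per aligned retained draw).
  The overlap statistic R = ∫ min(f̂_a, f̂_b) dx uses Gaussian KDEs with
  per-sample Silverman bandwidths on a 512-point grid over the union
  support padded by 3 bandwidths, trapezoid integration, clamped to
  [0, 1].  R ≤ 0.05 flags a pair as differing between informants; the
  rule is applied per pair without multiplicity correction (by design —
  the flagged set is descriptive).  Kullback–Leibler divergence is
  computed on the same grid with densities renormalized and floored at
  1e-12; both directions and the symmetrized mean are reported, and tiny
  negative quadrature error is clamped to zero.  A two-sample
  Kolmogorov–Smirnov test is provided with the documented caveat that
  posterior samples are autocorrelated, so its p-value is optimistic.
* **Syndrome geometry.**  A syndrome's position is the centroid of its
  member items' posterior-mean positions (a per-draw variant exists for
  uncertainty bands); similarity between syndromes is the cosine of their
  centroid vectors, reported as an 8×8 matrix per instrument.
* **Respondent profiles.**  Euclidean distances from each respondent's
  posterior-mean position to each syndrome centroid, clustered by
  K-means (k-means++, 25 restarts, fixed seed; k = 4 by default,
  configurable, no automatic selection).  In paired designs both
  informants measure the same respondents, so the recovery analyses
  concatenate the two instruments' distance profiles — two independent
  measurements of one latent group structure — which materially reduces
  the blur from position uncertainty.
* **Ranked pair tables.**  Because "most different pair" is ambiguous,
  pairs are ranked both by R ascending and by absolute MAP-distance
  difference descending, and both posterior-mean and MAP distances are
  emitted.

## Baselines and goodness of fit

Conventional comparisons (`lsirm.baselines`): syndrome sum scores
(per-respondent sums of non-missing member items) and their per-syndrome
Pearson correlations; per-item Cohen's κ on pairwise-complete respondents
with syndrome means; within-instrument item-pair Jaccard similarity
J = |A∩B| / |A∪B| and the between-instrument difference matrix with a
top-12 table.  Missing handling: pairwise-complete deletion for κ and
correlations, missing → 0 for Jaccard with the affected-cell count
reported (missingness is ~0.2 % in the emulated data, so the choice is
immaterial but explicit).

Goodness of fit (`lsirm.assessment`): in-sample classification of
observed responses by thresholding predicted probabilities at 0.5
(plug-in at posterior means by default; draw-averaged probabilities as an
option), reporting specificity TN/(TN+FP), sensitivity TP/(TP+FN) and
overall accuracy.  Zero denominators yield NaN plus an `undefined` flag,
never a silent 0.  Evaluation is deliberately in-sample: the question is
adequacy of fit, not prediction.

## Synthetic data generator

`lsirm.synthetic` draws paired-informant datasets from the generative
model itself, with study conditions emulating the motivating application
(two informants' reports on the same children):

* 662 respondents × 118 items by default; 8 syndromes × 13 items plus 14
  unassigned items.
* Syndrome poles on a circle of radius 1.5 with externalizing (AB, RBB)
  and internalizing (AD, WD, SC) groups in opposite half-planes and
  AP/TP/SP between, item spread 0.3 around the pole — giving within-group
  centroid cosines > 0.7 and a clear external–internal axis.
* Respondents cluster around 4 syndrome poles (spread 0.4), providing
  ground-truth labels for clustering recovery.
* β, θ ~ N(0, 1); the full-scale positive-response rates (0.27
  parent-report, 0.43 self-report, matching the reported means of the
  dichotomized instruments) are hit by bisecting a single global easiness
  offset against the exact expected rate under the truth — a reproducible
  calibration rather than hand-tuned β means.
* Cross-informant discrepancy is injected exactly as configured:
  instrument b's truth is instrument a's truth plus an easiness shift
  (default +1.5) on a designated set of unassigned items, a rigid
  displacement of one item cluster, and optional respondent-position
  jitter.
* Missingness is MCAR at rate 0.002 — a strict subcase of the MAR
  assumption the sampler makes, sufficient for validating the
  augmentation machinery but not a test of MAR sensitivity.

What passing recovery tests show — and what they do not: the data are
drawn from the fitted model family, so they validate the sampler,
alignment and discrepancy statistics, not the LSIRM's adequacy for real
questionnaire responses (no local item dependence beyond the latent
space, no ordinal response structure, no informative missingness, no
reporting-style artifacts).

## Known limitations and expected behavior at small scale

* At N = 400, P = 60 the posterior standard deviation of a single β_i is
  ≈ 0.29 — intrinsic (the between-chain spread of posterior means is ten
  times smaller), driven by the trade-off between an item's easiness and
  its position relative to the respondent cloud.  Two independently
  fitted replicates of the same truth with β spread ≈ 1 therefore show a
  β-vector correlation attenuated to about σ_β²/(σ_β² + σ_e²) ≈ 0.92,
  approaching 0.95+ only at the full 662 × 118 scale.  The zero-
  discrepancy run's correlation should be read against this ceiling.
* The overlap-flag rate under the null is well below 1 % of pairs, so the
  R ≤ 0.05 rule is conservative at these chain lengths.
* K-means cluster labels are arbitrary; all comparisons use the adjusted
  Rand index.
* The KS p-value on posterior distance samples ignores autocorrelation.
* `effective_sample_size` and the log-posterior trace are provided as
  diagnostics, not convergence gates.
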