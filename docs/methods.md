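# Methods

## Problem and design

An automated history-taking system produces one ranked top-10 DDx list
per patient (the *index* list).  Physicians query additional DDx
generators from the same history, twice independently per patient (two
*replicates*); the index list is constant across a patient's replicates,
the other generators' lists vary.  The question is whether fusing the
lists raises top-10 inclusion accuracy — membership of the confirmed
final diagnosis anywhere in the list; rank within the list does not enter
the outcome.  Diagnosis identity is exact id equality: the clinical
adjudication of synonyms that a real study performs by physician
discussion is out of scope and not reproducible mechanically.

## Fusion rules

For lists `L_1..L_m` (the first being the index list):

* **union** — the set union of candidate ids.  Output order (ascending
  best rank, ties by input priority then id) is deterministic but
  irrelevant to the accuracy metric.
* **weighted 1/n** — weight `w(d) = Σ_j 1/rank_j(d)` over the lists
  containing `d`; the top *k* (default 10) by descending weight form the
  output.  A diagnosis missing from a list simply gains no weight from it
  (no penalty term).  Ties in total weight break by smaller best
  single-list rank, then input-list priority, then lexicographic id —
  a deterministic, seed-free rule.  Tie handling matters to accuracy only
  when the truth sits exactly at the k-th boundary.  Weights are
  accumulated as exact rationals so genuinely tied sums (1/3 + 1/6 vs
  1/2) reach the tie-break rule instead of being ordered by float
  rounding; entries carry the weight as a float.
* **shared** — the intersection of all lists, ordered by index-list rank
  (the index system anchors the design); can be empty, and an empty list
  always scores a miss.

Set logic gives two theorems the test suite asserts on every cohort:
truth-in-union ⇔ truth in ≥ 1 input, so union accuracy ≥ every
single-list accuracy; truth-in-shared ⇒ truth in every input, so shared
accuracy ≤ every single-list accuracy.

## Paired evaluation

Replicate rows are treated as *independent* observations — the same
optimistic convention as the motivating design (103 cases × 2 replicates
× 2 other generators = 412 two-system rows; × 2 replicates = 206
three-system rows).  The pipeline logs a clustering caveat rather than
fitting a mixed model; a clustered alternative is a non-goal.  Index
accuracy is reported both per unique case (n = 103 framing) and per
expanded row, since both denominators are in common use.

* **CIs** — Clopper–Pearson exact binomial (statsmodels `beta` method).
  The exact interval is the one that reproduces printed bounds such as
  47/103 → 36%–56% (Wald and Wilson round the upper bound to 55%).  Exact
  intervals are conservative; a coverage test confirms ≥ 95% empirical
  coverage at n = 103, p = 0.46.
* **McNemar** — default is the exact two-sided binomial test on the
  discordant counts, `p = min(1, 2·P(X ≤ min(b,c)))`, `X ~ Bin(b+c, ½)`;
  a continuity-corrected chi-square variant `(|b−c|−1)²/(b+c)` is
  available by flag since published reports rarely state which was used.
  `b + c = 0` gives p = 1.
* **Logistic regression** — ML fit (statsmodels `Logit`,
  Newton/IRLS) of hit on the shared count treated as continuous, Wald SE
  from the observed information, reported as an odds ratio per one
  additional shared diagnosis with a 95% Wald CI.  Single-class outcomes,
  constant predictors, non-convergence and complete separation raise
  explicit errors instead of returning divergent estimates.
* The significance threshold (0.05 by convention) is surfaced in
  reporting only; no multiple-testing correction is applied.

## Synthetic cohort model

Each case draws a latent difficulty `D ~ N(shift·1[uncommon], sd²)`,
shared by all generators and replicates — a random intercept.  Generator
`g` hits the truth with probability `expit(skill_g − D)`; the shared
intercept induces the positive hit correlation that makes concordance
informative about accuracy.  With `difficulty_sd = 0` the hits are
independent Bernoulli, a mode kept for analytic checks (two-system union
accuracy → `1 − (1−p₁)(1−p₂)`).

When a generator hits, the truth's rank is truncated-geometric on 1..10
with parameter `truth_rank_geometric_p`; published reports typically do
not state where in the list correct diagnoses appeared, so this is a
sensitivity knob, not an empirical claim.  Distractor slots are drawn
without replacement either from a case-level pool shared by all
generators (probability `pool_overlap_weight`) or from a
generator-private pool; truth, shared pool and private pools are mutually
disjoint, so zero overlap weight yields disjoint supports and the
expected shared count rises monotonically with the weight.  Replicate-2
lists of non-index generators redraw each distractor slot with
probability `replicate_resample_prob` (hit status and truth rank are
case-level properties and are kept); the index list is cloned across
replicates.  Randomness uses one root seed with per-case substreams keyed
by a counter, so cohorts are bit-reproducible and prefix-stable under
changes of `n_cases`.

### Defaults (the emulated study conditions)

| parameter | default | rationale |
|---|---|---|
| `n_cases`, `n_replicates` | 103, 2 | cohort size and physician inputs of the emulated design |
| marginal hit rates (`study_config`) | 0.46 / 0.41 / 0.27 | observed marginals of the three systems; skills solved by Gauss–Hermite quadrature + Brent root-finding |
| `stratum_fraction_common` | 64/103 | common/uncommon split (uncommon ≈ rare-disease criterion, ≤ 1 per 2000) |
| `stratum_difficulty_shift` | 1.6 | solved from the ~58% vs ~26% common/uncommon index accuracies via the logit-normal approximation |
| `difficulty_sd` | 1.0 | a realistic case-mix spread giving moderate hit correlation |
| `truth_rank_geometric_p` | 0.35 | mild preference for high ranks; unconstrained by data |
| `pool_size_case`, `pool_overlap_weight` | 15, 0.55 | hypergeometric back-of-envelope targeting a pairwise shared-count median of 2 (range 0–6) and a three-way median of 1 (0–4) |
| `replicate_resample_prob` | 0.3 | physicians re-enter keywords, perturbing but not replacing a generator's list |
| `vocabulary_size` | 400 | ≥ 1 + pool_size·(1 + n_generators), so pools can be disjoint |

What the generator does *not* emulate: diagnosis synonymy and ontology
structure, rank-dependent truth placement calibrated to data, any
dependence of list content on case difficulty beyond the hit indicator,
or within-physician style.  Passing tests therefore demonstrate the
correctness and calibration of the analysis machinery, not clinical
performance of any real generator.  The concordance→accuracy association
the model induces is directionally correct (accuracy rises with the
shared count; slope significantly positive) but somewhat weaker than
real studies report, because only the truth and a single latent scalar
link the lists.

## Numerical choices

* Marginal calibration inverts `E[expit(s − D)]` over the two-component
  normal mixture with 80-node Gauss–Hermite quadrature and Brent's method
  on [−30, 30]; quadrature agrees with Monte-Carlo integration to < 0.5%.
* Weighted fusion uses exact rational weight arithmetic (see above).
* Cohort readers validate hard: ranks outside 1..10, duplicate
  (case, replicate, generator, rank) keys, duplicate diagnoses within a
  list and lists with ≠ 10 entries (an incomplete interview in the
  emulated design) are rejected with row-numbered messages.
* Degenerate inputs: empty list collections, fewer than two lists for the
  shared rule, empty strata (emitted as empty-marked cells, never zeros),
  and zero discordant pairs are all handled explicitly.

## Limitations

Replicate independence overstates effective sample size; exact CIs are
conservative; the logistic model treats the shared count as linear on the
log-odds scale; and all empirical statements produced by this package
about accuracy gains refer to the synthetic data-generating process
unless a user supplies a real cohort file.
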