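# Methods

`mrsmil` implements a multiple-instance-learning (MIL) classifier for
multi-label symptom data. A patient is a *bag*; each symptom the patient
presents is an *instance* (by default a one-hot vector over the symptom
vocabulary, optionally severity-scaled); the bag's label set holds one or
more syndrome classes. The method has three stages per class, followed by a
Bayes-rule differentiation step over all classes.

## Stage 1 — representative-symptom selection by minimum reference set

For a target class, bags are split one-vs-rest (a bag co-labeled with
several classes is positive for each of them: in this regime the positive
sample is small and the negative sample large). A candidate set of symptom
prototypes induces a *similarity embedding*: coordinate `j` of bag `B` is

    e_j(B) = max_{x in B} exp(-||x - p_j||^2 / sigma^2),

the best match of any instance of `B` to prototype `p_j` (the
most-similar-instance embedding used across the embedded-instance-selection
MIL family). `sigma` defaults to the median instance-prototype distance.

A candidate set is scored by the size of the **minimum reference set
(MRS)** it induces: starting from the empty set, the closest cross-class
pair of embedded bags (with at least one member still outside) is added,
and a manifold-ranking (MR) classifier seeded by the current set is re-run
over all labeled bags; the process stops at zero training error (the end
condition) or, if zero error is unreachable, when every bag has been
absorbed (the full set is returned with its residual error). A small MRS
means few labeled bags suffice to separate the class — the selection
criterion for a good symptom signature.

The MR classifier ranks bags on a Gaussian affinity graph
(`W_ij = exp(-d_ij^2 / 2 sigma_g^2)`, `sigma_g` = median nonzero pairwise
distance, min-Hausdorff bag distance by default) via

    F = (I - alpha * S)^{-1} Y,      S = D^{-1/2} W D^{-1/2},

with one-hot seed indicators in `Y`, each seed column divided by its
class's seed count, and argmax classification (ties to the negative
class). Both the closed-form solve and the damped power iteration are
implemented; the iterative fixed point is rescaled by `1/(1-alpha)` so the
two agree.

**alpha = 0.5, not the customary 0.99.** With heavy smoothing the two score
columns both collapse onto the graph's dominant eigenvector and differ only
at second order; on separable data the zero-error end condition then becomes
unreachable even with every bag seeded. At `alpha = 0.5` the direct seed
term stays comparable to the diffusion term, zero error is reached with
small reference sets on separable cohorts, and reference-set size remains a
discriminative score. Seed-count normalisation likewise prevents the large
negative class from outvoting the small positive one by seed mass alone.

**Search strategy.** Candidates (distinct instances of the positive bags)
are admitted to the pool ranked by smoothed *lift* — the ratio of
positive-bag to negative-bag frequency — which is the selection target
("dense among positives, sparse among negatives") made literal; under
multi-label co-occurrence, raw positive frequency would also admit
co-labeled classes' signature symptoms. The default search scores the
nested prefixes of this ranking and returns the prefix with the smallest
MRS (ties: shorter prefix). A step-wise greedy search (re-score every
remaining candidate at each step, add the minimiser) is available via
`SelectionConfig(strategy="greedy")` but is not the default: for one- or
two-prototype sets the embedding collapses many bags onto identical points
with conflicting labels, the MRS saturates near the number of bags, and the
early greedy choices degenerate into noise-chasing. On planted-signature
cohorts the ranked search recovers signatures with selected precision
0.82–0.92; the greedy variant reaches only 0.47–0.65.

**Scoring cost.** Candidate sets are scored on a deterministic stratified
subsample of at most `max_scoring_bags = 300` labeled bags (the reference
set's rationale — generalisation from few labeled bags — is exactly what
makes the capped scoring sound), with at most `max_candidates = 30`
candidates and prefixes up to `max_prototypes = 15`. Within one search,
reference-set generation is pruned exactly once its size exceeds the
incumbent best (branch-and-bound; the comparison outcome is unchanged).

## Stage 2 — per-class Gaussian mixture with EM and MDL

The positive bags are embedded on the class's selected prototypes and a
full-covariance Gaussian mixture is fitted by EM (k-means++ initialisation,
three restarts per k). The component count `k = 1..min(5, n-1)` is chosen
by minimum description length,

    MDL(k) = -loglik + (P/2) ln(n m),   P = (k-1) + k m + k m(m+1)/2,

ties to the smaller k. Numerical safeguards:

- ridge `1e-6 * trace(cov)/m` added to every covariance each M-step;
- an absolute per-coordinate variance floor (`GMMConfig.var_floor`,
  default 0.02), applied as an eigenvalue clip. Embedded symptom profiles
  are heavily duplicated; without the floor a component collapses onto a
  duplicate row, the likelihood is unbounded (MDL then always selects
  `k_max`) and the resulting spiky density assigns astronomically negative
  scores to slightly atypical bags. The floor is scaled to the unit-bounded
  embedding (coordinates in (0, 1]); set it to 0 for data on other scales.
- EM stops on relative log-likelihood change below `tol = 1e-6`, and keeps
  the previous parameters if a (rounding-scale, regularisation-induced)
  decrease is detected, so the reported likelihood trace is nondecreasing
  within 1e-9.

## Stage 3 — top-K maximum-posterior differentiation

Each class model carries its prior (positive-bag fraction). For a test bag,

    posterior(c) ∝ prior(c) * density_c(embedding_c(bag)),

computed in log space; if every density underflows, the posterior falls
back to the normalised priors. The K = 3 highest-posterior classes are
assigned (configurable; 3 matches a 7-class syndrome panel), with ties
broken by class vocabulary order.

Evaluation uses per-class counts A (bags assigned the class in their
top-K), B (of those, bags truly carrying it) and C (bags truly carrying
it), with precision = B/A, recall = B/C, and macro averages over classes
with C > 0; classes with A = 0 or C = 0 are flagged, and C = 0 classes are
excluded from the macro averages. Note the structural ceiling: every test
bag is assigned exactly K classes, so macro precision is bounded by roughly
mean(|label set|)/K, and with K = 3 of 7 classes any reasonable ranker
saturates recall near 1. Comparisons at K = 3 are therefore informative for
precision but barely for recall; the easy-preset sanity checks evaluate at
K = 1, where precision = recall = accuracy for single-label data.

## Synthetic cohorts

The generator emulates a clinical symptom-survey regime: 88 binary
symptoms, 7 syndrome classes, planted per-class signatures of 10 symptoms
in a chain construction where adjacent classes share
`round(overlap_fraction * signature_size)` symptoms. Per bag, the label-set
size is `1 + min(Poisson(0.8), 2)` (1–3 syndromes, mean ≈ 1.66); each
signature symptom of each assigned class appears with probability
`expression_prob = 0.8` (class-OR semantics), every other symptom with
`noise_rate = 0.05`; bags with fewer than two symptoms are resampled
(mirroring the usual inclusion criterion). Presets: `paper-like`
(the defaults above), `hard` (overlap 0.4, noise 0.1), `easy`
(single-label, expression 1, no noise/overlap — the fully separable sanity
regime; multi-label bags with shared symptoms are *not* separable under the
min-Hausdorff bag distance, since any shared symptom makes the distance 0),
and `small-sample` (the easy regime swept over 100–2000 bags).

What the generator does not emulate: real symptom co-occurrence structure,
label noise, missing records, severity gradations (severities are 1.0 by
default; a Beta option exists for stress tests), or correlated noise.
Passing tests therefore demonstrate the machinery recovers planted,
conditionally independent structure — not clinical performance.

## Experiment harness and problem sizes

`run_experiment` repeats (default 10×) a seeded 80/20 split, runs the full
per-class pipeline on the training split and reports per-class and macro
precision/recall means and standard deviations; `run_sweep` re-runs the
experiment across cohort sizes to produce the precision-vs-n curve. The
bundled experiments use cohorts of 300 bags (selection studies use 700) and
single splits per seed — sizes chosen so a study of 10 seeds completes on
one CPU in minutes while leaving per-class positive counts (≈65 at n=300)
in the small-sample regime the method targets.

The Bernoulli naive Bayes comparison arm (one-vs-rest sklearn
`BernoulliNB` on bag-level symptom indicators, top-K by posterior) is a
deliberately strong baseline under this generator, whose symptoms *are*
conditionally Bernoulli given the label set. On planted cohorts MRS-MIL
beats it on macro precision consistently (10/10 seeds in the bundled
study), while both methods sit at the top-3 recall ceiling described above
(naive Bayes at 1.0 in most seeds, MRS-MIL at 0.97–1.0), so a strict
recall comparison at K = 3 is uninformative in this regime.

## Determinism

Every source of randomness (generator, subsampling, k-means++ restarts,
splits) descends from explicit integer seeds through
`numpy.random.SeedSequence([seed, stage, index])`; identical seeds give
byte-identical reports. The greedy/ranked searches, tie-breaks, and pair
addition are fully deterministic (lowest-index ties).

## Known limitations

- "Minimum" reference set is the greedy construct, not a certified
  minimum (subset selection is combinatorial; a brute-force oracle in the
  test suite checks the small-n behaviour).
- All selected symptoms carry equal weight in the embedding; no
  representative degree per symptom.
- Mixture densities are compared across classes that live in different
  embedding spaces (dimension = per-class prototype count); the variance
  floor bounds, but does not remove, the resulting scale differences.
- No out-of-sample extension for the MR classifier: classification always
  re-ranks on the joint reference+query graph.
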