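# Methods

## Model

A binary naive Bayes classifier over attributes *A*₁…*A*ₙ stores class
priors p(c) and, per attribute, class-conditional probabilities. Continuous
attributes are interval-discretized: the attribute domain is sliced into
contiguous half-open intervals [lᵢⱼ, uᵢⱼ) and each interval carries one
probability per class — together a *chunk of expertise*
(*I*ᵢⱼ, p(*A*ᵢ∈*I*ᵢⱼ|c₁), p(*A*ᵢ∈*I*ᵢⱼ|c₂)). Discrete attributes carry a
value → per-class probability table. Prediction multiplies the prior with
the per-attribute conditionals of the intervals/values the observation
falls in (conditional independence assumption) and takes the most probable
class.

Numerical conventions:

- **Half-open intervals, clamped.** Membership is lᵢⱼ ≤ x < uᵢⱼ; values at
  or beyond the domain bounds clamp to the outermost intervals, so
  prediction is total on unseen data.
- **Log-space scoring with a probability floor.** Every factor is floored
  at 10⁻¹² before the log, so a chunk probability of exactly zero (possible
  after external edits) cannot produce NaN posteriors.
- **Deterministic tie-break.** Equal posteriors resolve to the first class
  in the declared label order.
- **Laplace smoothing.** Priors and all conditional tables are smoothed
  frequency estimates with pseudo-count ε = 1 by default; without smoothing
  a single empty bin would zero out the whole product.
- **Training discretization.** Equal-frequency binning by default (robust
  to the skewed distributions typical of clinical measurements);
  equal-width available. Duplicate quantile edges are merged with a
  warning; a constant attribute degrades to a single unit-width bin.
- **Missing values** are rejected at load time with the offending row
  indices; imputation is out of scope.
- Types carry k ≥ 2 classes, but the combination engine is validated for
  binary classifiers only and warns otherwise.

## Evaluation

Model quality is Youden's J-index: the unweighted mean of per-class
recalls of the confusion matrix (equivalently, balanced accuracy).
On class-balanced data J coincides with plain accuracy (*correctness*);
on unbalanced data it weighs rare labels equally, so constant and random
classifiers sit at 0.5 regardless of prevalence. A class absent from the
evaluation labels is excluded from the average with a warning rather than
producing NaN, so very small folds stay scorable.

Cross-validation is stratified k-fold (stratification protects the
J-index's per-class denominators on unbalanced data), repeated with
per-repeat seeds. Method comparisons use a paired t-test on fold-matched
scores; the one-tail variant tests strict superiority, two-tail parity.
Zero-variance differences are degenerate for the t statistic and map to
p = 1 (equal means) or p → 0 (constant nonzero shift), logged.

## The combination engine

Per continuous attribute, the sorted union of all experts' boundaries
(duplicates merged at 10⁻⁹ relative tolerance) defines the composite grid;
each expert's outermost intervals are first widened to the composite span,
mirroring the clamping convention, so every expert tiles the whole domain.
Each composite interval holds one edge per expert with:

- **Projected probabilities.** Width-proportional mass allocation:
  p(sub|c) = Σ_I p(I|c)·|sub∩I|/|I| (uniform-within-interval assumption).
  This is the unique rule that conserves each original interval's mass —
  sub-interval probabilities telescope back exactly, and a single-expert
  path sums to 1 per class with no renormalization. An `inherit` mode
  (copy the enclosing interval's probability) is exposed for ablation; it
  deliberately breaks conservation.
- **Pheromone** τ, initialized to τ₀ = 1, floored at 10⁻¹².
- **Visibility** η = sum of the edge's conditional probabilities.

An ant picks one edge per interval with probability ∝ τᵅηᵝ (uniform
fallback when all weights vanish) by roulette-wheel draw. Mixed-expert
compositions are renormalized per class before scoring (default on,
flag for ablation): without renormalization the product is no longer a
probability model — though note renormalization also rescales each class's
likelihood by a constant and thereby shifts the decision threshold, which
is precisely one of the degrees of freedom the search exploits.

Fitness of a candidate composition is the J-index, on the context data, of
the base classifier with that single attribute swapped in. During one
attribute's optimization the grid and all other attributes are fixed, so
the implementation precomputes the other attributes' log-score
contribution per row once and reduces each path evaluation to an O(rows)
table lookup; a unit test pins this fast path to the plain
assemble-and-score route at 10⁻¹² tolerance.

Pheromone dynamics per iteration: one global evaporation τ ← (1−ρ)τ, then
every ant of the iteration deposits Δτ = Q·J on its tour's edges (the
deposit is not restricted to the best ant). Randomness derives from one
master seed via child streams per (attribute, iteration, ant), so runs are
bit-reproducible.

Whole-classifier assembly: the warm start is the pool member with the
highest context J; attributes are optimized sequentially in schema order
(configurable), each accepted composition carried forward so later
attributes adapt to earlier choices; a composition is accepted only if the
candidate's context J does not fall below the incumbent's. The warm
start's class priors are kept rather than re-estimated from the context:
under the J-index every class weighs equally, and replacing the priors
with the context prevalence demonstrably moves the decision rule away from
the balanced-recall optimum on unbalanced contexts (measured as a
systematic held-out J drop on synthetic scenarios). The search shapes
conditional structure only, and threshold adjustments it needs are
expressible through per-class renormalization.

An exhaustive-enumeration oracle (all N^m paths, lexicographic tie-break,
capped at 10,000 paths) provides the exact optimum on small graphs for
testing; the colony is checked to match it on ≥95% of seeded small
instances at a budget of 50 evaluations per path in the space.

## Benchmarks

- **Best expert**: argmax context J over the pool, ties to the lowest index.
- **Data combination**: one classifier retrained on the concatenated
  training data. When pools are simulated from the CV training folds, the
  union of the pool's training data is the training folds themselves.
- **Boosting**: AdaBoost.M1 by *selection from the fixed pool* — each round
  picks the member minimizing the weighted error ε, weights it
  ½ln((1−ε)/ε), and reweights the sample multiplicatively; ε = 0 caps the
  weight and stops, ε ≥ 0.5 discards the round and stops. A retrain mode
  (fresh classifier per round on a weight-resampled bootstrap) is exposed
  since the classical algorithm retrains; default is pool selection, which
  matches combining pre-existing classifiers. Rounds default to 25.
- **Bagging**: bootstrap resamples of the training data, one classifier
  per bag, majority vote, ties to the first label. Single-class bootstrap
  draws are skipped.

## Synthetic data

The generator emulates clinical-style tables: a binary label with
configurable prevalence, continuous attributes drawn from per-class
Gaussians (optionally clipped to a domain), discrete attributes from
per-class categorical tables. Informativeness is the standardized
separation of class means, or a per-class spread contrast (equal means,
different sds) for band-shaped markers where the signal lives in interval
*placement* rather than in a threshold. Expert pools are simulated by
training classifiers on random attribute subsets of random halves of a
training sample (2 per subset), ranking by training error and keeping the
top m (defaults: 20 subsets, top 9); subset experts are padded to the full
schema with class-independent uniform compositions, the neutral completion
that cancels in the posterior.

What the generator does **not** emulate: correlated attributes (the data
satisfies the naive independence assumption by construction), non-Gaussian
class-conditional shapes, measurement error, or missingness. Passing tests
on these cohorts therefore demonstrate the machinery under the model's own
assumptions, not performance on real clinical data.

### The planted-optimum scenario

The parameter-recovery test bed plants a structure that is recoverable
only by *combination*, since that is the capability under test:

- the informative attribute is a band marker — equal class means,
  per-class sds (1.6, 0.7), prevalence 0.5, so the positive class
  concentrates in a central band and the optimal classifier needs two
  well-placed cuts (a single threshold cannot express it);
- expert 0 (the true-structure expert) is trained on a clean draw
  (n = 250) and is the only pool member with full-strength conditional
  probabilities, but on a crude 4-bin equal-width slicing whose cuts miss
  the band edges;
- the other 8 experts are trained on draws whose labels were flipped with
  probability 0.35 (degraded related contexts): attenuated, noisy
  probabilities, but varied binnings (2–6 bins, alternating
  equal-frequency/equal-width) whose quantile cuts land near the band
  edges.

No single expert is optimal; the composite grid contains the cuts the
band needs, and the colony — guided by the context training folds —
recombines the strong probabilities with the sharper cut structure. The
recovery study cross-validates each scenario (10-fold), scores composite
and best expert on held-out folds, and compares seed-level means with a
one-tail paired t-test over 20 independent scenario seeds; 20 seeds
(rather than the minimum 10) because the per-seed gain is small relative
to fold noise and an honest stochastic pass needs the extra power.

## Problem sizes and budgets

Study sizes are chosen so the whole suite runs in minutes on one CPU
while the statistics remain meaningful: contexts of 2,000 rows for the
recovery and chance-level studies, 9-expert pools, 10-fold CV, 20
scenario seeds. The recovery study runs the colony at 10 iterations × 8
ants per attribute: the context folds are modest samples, and a larger
search measurably overfits them (training J keeps rising while held-out J
falls) — the same overfitting concern that motivates conservative
published parameter profiles. The four published profiles (hd-1/hd-2/
hd-3/ctg, e.g. ctg: NC = 100, NA = 50, Q = 2.0, ρ = 0.03, α = 2.0,
β = 2.0) are shipped as presets for full-scale runs.

## Known limitations

- The engine is validated for binary classification only.
- Whole-classifier-level search (constructing all attributes
  simultaneously) is out of scope; only per-attribute sequential assembly
  is implemented.
- Chunk *mutation* beyond re-slicing by projection is not implemented;
  the search recombines and re-slices existing expertise.
- `uniformity`/`stability` thresholds in the predictor report (u_min = 0.2,
  s_min = 0.8) are an operationalization of qualitative notions; verdicts
  are labelled as such and are not clinically validated.
- Bagging can return fewer members than requested when bootstrap draws
  miss a class; the ensemble falls back to a single full-data learner in
  the degenerate case.
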