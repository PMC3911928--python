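"""Combine a pool of simulated experts with the ant colony.

Simulates a pool of pre-existing naive Bayes "experts" (each trained on a
random attribute subset of a random half of the data, imitating partial
opinions), then lets the colony recombine their chunks of expertise guided
by context data. Prints each expert's context J-index, the best expert's
score, and the composite's score: the composite should match or beat the
best single expert on the data that guided the search.
"""

import antbayes as ab

specs = [ab.continuous_spec("marker", separation=2.0), ab.continuous_spec("noise0")]
context = ab.generate_dataset(ab.CohortConfig(400, 0.4, specs, seed=11))

pool = ab.generate_expert_pool(context, n_subsets=5, top_m=4, seed=7)
for i, expert in enumerate(pool):
    print(f"expert {i}: trained on {expert.metadata['subset']}, "
          f"context J = {ab.j_score(expert, context):.3f}")

config = ab.ACOConfig(n_iterations=10, n_ants=8, seed=0)
composite, traces = ab.combine_classifiers(pool, context, config)

best = ab.best_expert(pool, context)
print(f"\nbest expert J:  {ab.j_score(best, context):.3f}")
print(f"composite J:    {ab.j_score(composite, context):.3f}")
for attribute, trace in traces.items():
    print(f"  {attribute}: best-of-search J = {trace.best_j:.3f} "
          f"({trace.evaluations_count} evaluations)")
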