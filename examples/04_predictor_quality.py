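"""Judge attributes as good or poor predictors from repeated combination runs.

Runs the colony several times with different seeds on the same context,
collects each attribute's final composition per run, and scores every
attribute on two axes: between-class separation of its conditional
distributions (total-variation distance; near 0 = uninformative) and
stability of the composition across runs. Attributes that are stable and
clearly non-uniform are flagged good predictors; attributes near-uniform
in every run are poor predictors.
"""

import antbayes as ab

specs = [ab.continuous_spec("marker", separation=2.0), ab.continuous_spec("noise0")]
context = ab.generate_dataset(ab.CohortConfig(400, 0.4, specs, seed=11))
pool = ab.generate_expert_pool(context, n_subsets=5, top_m=4, seed=7)

runs = {name: [] for name, _ in context.schema}
for seed in range(4):
    config = ab.ACOConfig(n_iterations=8, n_ants=6, seed=seed)
    composite, _ = ab.combine_classifiers(pool, context, config)
    for comp in composite.continuous_attrs:
        runs[comp.attribute_name].append(comp)

report = ab.predictor_report(runs)
print(report.to_markdown())
print("\nuniformity = between-class TV distance (0 uninformative, 1 disjoint);")
print("stability = 1 - mean pairwise TV across runs on the shared grid.")
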