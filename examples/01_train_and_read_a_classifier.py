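"""Train a naive Bayes classifier on a synthetic cohort and read its chunks.

Builds a small clinical-style cohort (one informative biomarker, one noise
attribute, 40% prevalence), fits an interval-discretized naive Bayes
classifier, and prints its chunks of expertise — one human-readable
sentence per (interval, conditional probabilities) triplet — plus the
training J-index (balanced accuracy; 0.5 is chance, 1.0 is perfect).
"""

import antbayes as ab

specs = [
    ab.continuous_spec("marker", separation=2.0),  # class means 2 sd apart
    ab.continuous_spec("noise0"),                  # carries no class signal
]
cohort = ab.generate_dataset(ab.CohortConfig(400, 0.4, specs, seed=11))

model = ab.train_naive_bayes(cohort, n_bins=4)

print(ab.render_chunks(model))
print()
print(f"class priors: {[round(p, 3) for p in model.class_priors]}")
print(f"training J-index: {ab.j_score(model, cohort):.3f}")
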