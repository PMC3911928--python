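"""Cross-validated comparison of the composite against the four benchmarks.

Runs the full experiment harness on a synthetic cohort: per stratified CV
fold, an expert pool is simulated from the training folds, the colony
builds a composite (BC_new), and four benchmarks are built on the same
folds — best expert (BC_best), retraining on the pooled data (BC_all_data),
AdaBoost over the pool (BC_boost), and bagging (BC_bagg). All five are
scored by J-index on the held-out fold; paired t-tests compare BC_new
against each benchmark (one-tail for strict superiority over BC_best /
BC_all_data, two-tail for parity with boosting and bagging).
"""

import antbayes as ab
from antbayes.experiments import ExperimentConfig

specs = [
    ab.continuous_spec("marker", separation=1.5),
    ab.continuous_spec("secondary", separation=0.8),
    ab.continuous_spec("noise0"),
]
config = ExperimentConfig(
    cohort=ab.CohortConfig(500, 0.4, specs, seed=2),
    cv_folds=5,
    seed=2,
    pool_params={"n_subsets": 6, "top_m": 5},
    train_params={"n_bins": 4},
    aco_overrides={"n_iterations": 8, "n_ants": 6},
    boost_rounds=10,
    n_bags=5,
)

report = ab.run_experiment(config)
print(report.to_markdown())
print("\np-values test BC_new against each benchmark on fold-paired J scores.")
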