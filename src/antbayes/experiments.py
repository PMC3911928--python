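"""Experiment orchestration: CV harness over the five methods, hypotheses H1-H4.

One experiment cross-validates, on the same stratified folds, the
ACO-combined classifier (BC_new) against four benchmarks: the best pool
member (BC_best), a single classifier retrained on the pooled training data
(BC_all_data), AdaBoost over the pool (BC_boost) and bagging (BC_bagg).
Hypotheses: H1/H2 — BC_new strictly better than BC_best / BC_all_data
(one-tail paired t-test); H3/H4 — BC_new at least as good as boosting /
bagging (reported two-tail).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import StratifiedKFold

from .aco import ACOConfig, OptimizationTrace, combine_classifiers
from .bayes import Dataset, NaiveBayesClassifier, train_naive_bayes
from .benchmarks import WeightedEnsemble, adaboost_pool, bagging_pool, best_expert, data_combination
from .evaluation import ComparisonReport, EvaluationResult, confusion_matrix, j_index, paired_t_test
from .synthetic import CohortConfig, generate_dataset, generate_expert_pool

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "ACO_PRESETS",
    "load_config",
    "planted_recovery_study",
]

log = logging.getLogger(__name__)

#: named parameter presets for the colony, one per published experiment profile
ACO_PRESETS: dict[str, dict] = {
    "hd-1": dict(n_iterations=150, n_ants=100, delta=1.0, rho=0.02, alpha=2.0, beta=1.0),
    "hd-2": dict(n_iterations=120, n_ants=70, delta=1.0, rho=0.04, alpha=3.0, beta=2.0),
    "hd-3": dict(n_iterations=150, n_ants=100, delta=1.0, rho=0.02, alpha=2.0, beta=1.0),
    "ctg": dict(n_iterations=100, n_ants=50, delta=2.0, rho=0.03, alpha=2.0, beta=2.0),
}

METHODS = ("BC_new", "BC_best", "BC_all_data", "BC_boost", "BC_bagg")

HYPOTHESES = {
    "H1": ("BC_best", "one"),
    "H2": ("BC_all_data", "one"),
    "H3": ("BC_boost", "two"),
    "H4": ("BC_bagg", "two"),
}


@dataclass
class ExperimentConfig:
    """Everything one experiment needs; loadable from YAML."""

    dataset_path: str | None = None
    label_column: str = "label"
    column_kinds: dict = field(default_factory=dict)
    cohort: CohortConfig | None = None
    expert_paths: list[str] = field(default_factory=list)
    pool_params: dict = field(default_factory=dict)  # n_subsets, top_m, ...
    train_params: dict = field(default_factory=dict)  # n_bins, binning, smoothing
    aco_preset: str | None = None
    aco_overrides: dict = field(default_factory=dict)
    attribute_order: list[str] | None = None
    cv_folds: int = 10
    cv_repeats: int = 1
    seed: int = 0
    benchmarks: list[str] = field(default_factory=lambda: list(METHODS[1:]))
    boost_rounds: int = 25
    n_bags: int = 10
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("config error at cv_folds: must be >= 2")
        if self.dataset_path is None and self.cohort is None:
            raise ValueError("config error: either dataset_path or cohort is required")
        for b in self.benchmarks:
            if b not in METHODS[1:]:
                raise ValueError(f"config error at benchmarks: unknown method {b!r}")
        if self.aco_preset is not None and self.aco_preset not in ACO_PRESETS:
            raise ValueError(
                f"config error at aco_preset: {self.aco_preset!r} not in {sorted(ACO_PRESETS)}"
            )

    def aco_config(self) -> ACOConfig:
        params = dict(ACO_PRESETS[self.aco_preset]) if self.aco_preset else {}
        params.update(self.aco_overrides)
        params.setdefault("seed", self.seed)
        return ACOConfig(**params)

    def load_data(self) -> Dataset:
        if self.dataset_path is not None:
            return Dataset.from_csv(self.dataset_path, self.label_column, self.column_kinds)
        return generate_dataset(self.cohort)


def load_config(path) -> ExperimentConfig:
    """Read an experiment configuration from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort = None
    if "cohort" in raw:
        from .synthetic import continuous_spec, discrete_spec

        c = raw.pop("cohort")
        specs = []
        for s in c.get("attributes", []):
            if s.get("kind", "continuous") == "continuous":
                specs.append(
                    continuous_spec(
                        s["name"],
                        separation=s.get("separation", 0.0),
                        sd=s.get("sd", 1.0),
                        center=s.get("center", 0.0),
                        domain=tuple(s["domain"]) if "domain" in s else None,
                    )
                )
            else:
                specs.append(discrete_spec(s["name"], s["values"], s["class_probs"]))
        cohort = CohortConfig(
            n_rows=c["n_rows"],
            class_prevalence=c.get("class_prevalence", 0.5),
            attribute_specs=specs,
            seed=c.get("seed", raw.get("seed", 0)),
        )
    known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"config error: unknown fields {sorted(unknown)}")
    return ExperimentConfig(cohort=cohort, **raw)


def _fold_methods(
    cfg: ExperimentConfig,
    train: Dataset,
    experts: Sequence[NaiveBayesClassifier] | None,
    fold_seed: int,
) -> dict[str, object]:
    """Build BC_new and the enabled benchmarks on one training split."""
    if experts is None:
        pool = generate_expert_pool(
            train,
            seed=fold_seed,
            train_params=cfg.train_params,
            **cfg.pool_params,
        )
    else:
        pool = list(experts)
    aco = cfg.aco_config()
    aco = dataclasses.replace(aco, seed=fold_seed)
    models: dict[str, object] = {}
    composite, traces = combine_classifiers(pool, train, aco, cfg.attribute_order)
    models["BC_new"] = composite
    models["_traces"] = traces
    if "BC_best" in cfg.benchmarks:
        models["BC_best"] = best_expert(pool, train)
    if "BC_all_data" in cfg.benchmarks:
        # in-house pools are trained on subsets of this very training split,
        # so the union of their training data is the split itself
        models["BC_all_data"] = data_combination([train], **cfg.train_params)
    if "BC_boost" in cfg.benchmarks:
        models["BC_boost"] = adaboost_pool(pool, train, rounds=cfg.boost_rounds)
    if "BC_bagg" in cfg.benchmarks:
        models["BC_bagg"] = bagging_pool(
            lambda d: train_naive_bayes(d, **cfg.train_params),
            train,
            n_bags=cfg.n_bags,
            seed=fold_seed,
        )
    return models


def _j_of(model, data: Dataset) -> float:
    if isinstance(model, WeightedEnsemble):
        preds = model.predict_frame(data.X)
        labels = model.class_labels
    else:
        preds = model.predict_frame(data.X)
        labels = model.class_labels
    return j_index(confusion_matrix(data.y, preds, labels=labels))


def run_experiment(
    cfg: ExperimentConfig,
    experts: Sequence[NaiveBayesClassifier] | None = None,
) -> ComparisonReport:
    """Repeated stratified k-fold comparison of BC_new against the benchmarks.

    Per fold, every method is built on the training folds (the pool is
    loaded from ``expert_paths``/``experts`` if given, else simulated from
    the training folds) and scored by J-index on the held-out fold. The
    report aggregates fold scores and tests H1-H4 with fold-paired t-tests.
    """
    data = cfg.load_data()
    if experts is None and cfg.expert_paths:
        experts = [NaiveBayesClassifier.from_json(p) for p in cfg.expert_paths]
    method_names = ["BC_new"] + [b for b in METHODS[1:] if b in cfg.benchmarks]
    scores: dict[str, list[float]] = {m: [] for m in method_names}
    all_traces: list[dict[str, OptimizationTrace]] = []
    for r in range(cfg.cv_repeats):
        splitter = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed + r)
        for f, (train_idx, test_idx) in enumerate(splitter.split(data.X, data.y)):
            train = data.subset_rows(train_idx)
            test = data.subset_rows(test_idx)
            fold_seed = cfg.seed + 104729 * r + 7919 * f
            models = _fold_methods(cfg, train, experts, fold_seed)
            all_traces.append(models.pop("_traces"))
            for name in method_names:
                scores[name].append(_j_of(models[name], test))
            log.info("repeat %d fold %d: %s", r, f,
                     {m: round(scores[m][-1], 3) for m in method_names})
    results = {
        m: EvaluationResult(np.asarray(scores[m]), n_folds=cfg.cv_folds, n_repeats=cfg.cv_repeats)
        for m in method_names
    }
    p_values, tails = {}, {}
    for hyp, (other, tail) in HYPOTHESES.items():
        if other in method_names:
            p_values[other] = paired_t_test(scores["BC_new"], scores[other], tail=tail)
            tails[other] = f"{tail} ({hyp})"
    report = ComparisonReport(method_names, results, p_values, tails, reference="BC_new")
    if cfg.output_dir:
        _write_outputs(cfg, report, scores, all_traces)
    return report


def planted_recovery_study(
    master_seed: int = 0,
    n_seeds: int = 20,
    cv_folds: int = 10,
    aco_params: dict | None = None,
    scenario_params: dict | None = None,
) -> dict:
    """Parameter-recovery comparison on the planted-optimum scenario.

    For each of ``n_seeds`` derived seeds, a fresh scenario (fixed expert
    pool plus context) is cross-validated: per fold the colony combines the
    pool guided by the training folds, and both the composite and the best
    pool member are scored on the held-out fold. Seed-level mean J values
    are compared with a one-tail paired t-test (composite > best expert).

    The colony runs at a deliberately small budget (10 iterations of 8
    ants by default): the context folds are modest samples and a larger
    search mostly fits their noise — the same overfitting concern that
    drives the published parameter settings.
    """
    from .benchmarks import best_expert
    from .evaluation import j_score

    aco_params = dict(aco_params or {"n_iterations": 10, "n_ants": 8})
    scenario_params = dict(scenario_params or {})
    ss = np.random.SeedSequence(master_seed)
    seeds = [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n_seeds)]
    j_new, j_best = [], []
    for seed in seeds:
        from .synthetic import planted_optimum_scenario

        sc = planted_optimum_scenario(seed, **scenario_params)
        data = sc.context
        cfg = ACOConfig(seed=seed, **aco_params)
        fold_new, fold_best = [], []
        splitter = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed % 2**31)
        for train_idx, test_idx in splitter.split(data.X, data.y):
            train = data.subset_rows(train_idx)
            test = data.subset_rows(test_idx)
            composite, _ = combine_classifiers(sc.experts, train, cfg)
            incumbent = best_expert(sc.experts, train)
            fold_new.append(j_score(composite, test))
            fold_best.append(j_score(incumbent, test))
        j_new.append(float(np.mean(fold_new)))
        j_best.append(float(np.mean(fold_best)))
        log.info("scenario seed %d: J_new %.4f J_best %.4f", seed, j_new[-1], j_best[-1])
    p = paired_t_test(j_new, j_best, tail="one")
    return {
        "seeds": seeds,
        "j_new": j_new,
        "j_best": j_best,
        "mean_j_new": float(np.mean(j_new)),
        "mean_j_best": float(np.mean(j_best)),
        "mean_gain": float(np.mean(j_new) - np.mean(j_best)),
        "p_value": p,
    }


def _write_outputs(cfg, report, scores, all_traces) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_frame().to_csv(out / "report.csv")
    (out / "report.md").write_text(report.to_markdown() + "\n")
    # fold-level scores, boxplot-ready (one column per method)
    pd.DataFrame(scores).to_csv(out / "fold_scores.csv", index=False)
    rows = []
    for fold, traces in enumerate(all_traces):
        for attribute, tr in traces.items():
            for it, best in enumerate(tr.best_so_far):
                rows.append({"fold": fold, "attribute": attribute, "iteration": it, "best_j": best})
    pd.DataFrame(rows).to_csv(out / "aco_trace.csv", index=False)
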