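"""Comparison methods: best expert, pooled-data retraining, boosting, bagging.

Boosting operates by *selection from the fixed expert pool* (each round
picks the pool member with the lowest weighted error), with an optional
retrain mode that fits a fresh classifier on the reweighted sample instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .bayes import Dataset, NaiveBayesClassifier, train_naive_bayes
from .evaluation import j_score

__all__ = [
    "WeightedEnsemble",
    "best_expert",
    "data_combination",
    "adaboost_pool",
    "bagging_pool",
    "ensemble_predict",
]

log = logging.getLogger(__name__)

#: member weight assigned when a boosting round achieves zero weighted error
MAX_BOOST_WEIGHT = 0.5 * np.log((1.0 - 1e-8) / 1e-8)


@dataclass
class WeightedEnsemble:
    members: list[NaiveBayesClassifier]
    weights: list[float]
    combination: str = "weighted_vote"  # or "majority_vote"

    def __post_init__(self) -> None:
        if len(self.members) != len(self.weights):
            raise ValueError("one weight per member required")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")
        if self.combination == "weighted_vote" and not any(w > 0 for w in self.weights):
            raise ValueError("weighted vote needs at least one positive weight")
        if self.combination not in ("weighted_vote", "majority_vote"):
            raise ValueError(f"unknown combination {self.combination!r}")

    @property
    def class_labels(self) -> list:
        return self.members[0].class_labels

    def predict_frame(self, X: pd.DataFrame) -> np.ndarray:
        labels = self.class_labels
        votes = np.zeros((len(X), len(labels)))
        for member, w in zip(self.members, self.weights):
            preds = member.predict_frame(X)
            weight = w if self.combination == "weighted_vote" else 1.0
            for i, lbl in enumerate(labels):
                votes[:, i] += weight * (preds == lbl)
        idx = np.argmax(votes, axis=1)  # ties break to the first label
        return np.asarray(labels, dtype=object)[idx]

    def to_dict(self) -> dict:
        return {
            "members": [m.to_dict() for m in self.members],
            "weights": [float(w) for w in self.weights],
            "combination": self.combination,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WeightedEnsemble":
        return cls(
            [NaiveBayesClassifier.from_dict(m) for m in d["members"]],
            list(d["weights"]),
            d["combination"],
        )


def best_expert(
    experts: Sequence[NaiveBayesClassifier], context: Dataset
) -> NaiveBayesClassifier:
    """Pool member with the highest context J-index; ties break to the
    lowest pool index."""
    if not experts:
        raise ValueError("empty expert pool")
    scores = [j_score(e, context) for e in experts]
    return experts[int(np.argmax(scores))]


def data_combination(
    training_sets: Sequence[Dataset], **train_params
) -> NaiveBayesClassifier:
    """Concatenate all training sets and fit one classifier on the union."""
    if not training_sets:
        raise ValueError("no training sets")
    schema = training_sets[0].schema
    for ds in training_sets[1:]:
        if ds.schema != schema:
            raise ValueError("training sets have incompatible schemas")
    pooled = Dataset(
        pd.concat([ds.X for ds in training_sets], ignore_index=True),
        pd.concat([ds.y for ds in training_sets], ignore_index=True),
        list(schema),
    )
    return train_naive_bayes(pooled, **train_params)


def adaboost_pool(
    pool: Sequence[NaiveBayesClassifier],
    data: Dataset,
    rounds: int = 25,
    retrain: bool = False,
    **train_params,
) -> WeightedEnsemble:
    """AdaBoost.M1 over a fixed pool of binary classifiers.

    Each round selects the member minimizing the weighted error eps on the
    current data weights, receives weight 0.5 * ln((1 - eps) / eps), and the
    data weights are updated multiplicatively and renormalized. A perfect
    round (eps = 0) gets a capped weight and stops early; eps >= 0.5 discards
    the round and ends the loop. With ``retrain`` a fresh classifier is fit
    on a weight-resampled bootstrap each round instead of pool selection.
    """
    if not pool and not retrain:
        raise ValueError("empty pool")
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    n = len(data)
    y = data.y.to_numpy()
    w = np.full(n, 1.0 / n)
    rng = np.random.default_rng(train_params.pop("seed", 0))
    members: list[NaiveBayesClassifier] = []
    alphas: list[float] = []
    pool_correct = None
    if not retrain:
        pool_correct = [m.predict_frame(data.X) == y for m in pool]
    for _ in range(rounds):
        if retrain:
            idx = rng.choice(n, size=n, replace=True, p=w)
            member = train_naive_bayes(data.subset_rows(idx), **train_params)
            correct = member.predict_frame(data.X) == y
        else:
            errors = [float(w[~c].sum()) for c in pool_correct]
            best = int(np.argmin(errors))
            member, correct = pool[best], pool_correct[best]
        eps = float(w[~correct].sum())
        if eps >= 0.5:
            log.info("boosting stopped: weighted error %.3f >= 0.5", eps)
            break
        if eps <= 0.0:
            members.append(member)
            alphas.append(MAX_BOOST_WEIGHT)
            log.info("boosting stopped early: perfect member")
            break
        alpha = 0.5 * np.log((1.0 - eps) / eps)
        members.append(member)
        alphas.append(alpha)
        w = w * np.exp(np.where(correct, -alpha, alpha))
        w /= w.sum()
    if not members:
        # no member beat chance on the initial weights; fall back to the
        # single best so the ensemble stays well defined
        fallback = best_expert(pool, data) if pool else train_naive_bayes(data, **train_params)
        members, alphas = [fallback], [1.0]
    return WeightedEnsemble(members, alphas, "weighted_vote")


def bagging_pool(
    learner: Callable[[Dataset], NaiveBayesClassifier],
    data: Dataset,
    n_bags: int = 10,
    seed: int = 0,
) -> WeightedEnsemble:
    """Bootstrap-aggregated ensemble: one classifier per resample, majority vote."""
    if n_bags < 1:
        raise ValueError("n_bags must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(data)
    members = []
    for _ in range(n_bags):
        idx = rng.integers(0, n, size=n)
        bag = data.subset_rows(idx)
        if bag.y.nunique() < 2:  # resample until both classes appear
            continue
        members.append(learner(bag))
    if not members:
        members = [learner(data)]
    return WeightedEnsemble(members, [1.0] * len(members), "majority_vote")


def ensemble_predict(ens: WeightedEnsemble, x) -> object:
    """Vote of the ensemble on one observation mapping/series."""
    row = pd.DataFrame([dict(x)])
    return ens.predict_frame(row)[0]
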