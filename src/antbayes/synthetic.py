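"""Synthetic clinical-style cohorts and simulated expert pools.

Datasets emulate the structure the method assumes: a binary outcome with
configurable prevalence, continuous attributes drawn from per-class
Gaussians (informative when the class means differ, pure noise otherwise)
clipped to their domain, and discrete attributes drawn from per-class
categorical tables. Expert pools are simulated by training classifiers on
random attribute subsets of random halves of a training sample and keeping
the ones with the lowest training error — each expert is a partial,
noisy "opinion" about the same prediction problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .bayes import (
    CONTINUOUS,
    DISCRETE,
    AttributeComposition,
    Dataset,
    DiscreteAttributeTable,
    ExpertiseChunk,
    Interval,
    NaiveBayesClassifier,
    train_naive_bayes,
)
from .evaluation import j_score

__all__ = [
    "AttributeSpec",
    "CohortConfig",
    "PlantedScenario",
    "generate_dataset",
    "generate_expert_pool",
    "planted_optimum_scenario",
    "continuous_spec",
    "discrete_spec",
]


@dataclass
class AttributeSpec:
    """Distributional recipe for one attribute.

    For continuous attributes ``params`` holds per-class ``means`` and
    ``sds``; informativeness is the standardized separation of the class
    means. For discrete attributes ``params`` holds per-class value
    probability lists over ``values``.
    """

    name: str
    kind: str
    params: dict
    domain: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind == CONTINUOUS:
            if any(sd <= 0 for sd in self.params["sds"]):
                raise ValueError(f"{self.name!r}: standard deviations must be positive")
        elif self.kind == DISCRETE:
            for probs in self.params["class_probs"]:
                if abs(sum(probs) - 1.0) > 1e-9:
                    raise ValueError(f"{self.name!r}: value probabilities must sum to 1")
        else:
            raise ValueError(f"unknown kind {self.kind!r}")


def continuous_spec(
    name: str,
    separation: float = 0.0,
    sd: float = 1.0,
    center: float = 0.0,
    domain: tuple[float, float] | None = None,
    class_sds: tuple[float, float] | None = None,
) -> AttributeSpec:
    """Gaussian attribute whose class means sit ``separation`` sds apart.

    ``class_sds`` overrides the common ``sd`` with per-class spreads: equal
    means with unequal spreads give a band-shaped marker (one class
    concentrated in a central band, the other in the flanks), the structure
    where interval placement itself carries the class signal.
    """
    half = 0.5 * separation * sd
    return AttributeSpec(
        name,
        CONTINUOUS,
        {"means": (center - half, center + half), "sds": class_sds or (sd, sd)},
        domain,
    )


def discrete_spec(name: str, values: Sequence, class_probs: Sequence[Sequence[float]]) -> AttributeSpec:
    return AttributeSpec(name, DISCRETE, {"values": list(values), "class_probs": [list(p) for p in class_probs]})


@dataclass
class CohortConfig:
    n_rows: int
    class_prevalence: float
    attribute_specs: list[AttributeSpec]
    seed: int = 0
    class_labels: tuple = (0, 1)

    def __post_init__(self) -> None:
        if self.n_rows < 2:
            raise ValueError("n_rows must be >= 2")
        if not (0.0 < self.class_prevalence < 1.0):
            raise ValueError("class_prevalence must lie in (0, 1)")


def generate_dataset(cfg: CohortConfig) -> Dataset:
    """Seeded draw of a cohort: labels by prevalence, attributes per class."""
    rng = np.random.default_rng(cfg.seed)
    y_codes = (rng.random(cfg.n_rows) < cfg.class_prevalence).astype(int)
    columns = {}
    schema = []
    for spec in cfg.attribute_specs:
        if spec.kind == CONTINUOUS:
            means = np.asarray(spec.params["means"])[y_codes]
            sds = np.asarray(spec.params["sds"])[y_codes]
            values = rng.normal(means, sds)
            if spec.domain is not None:
                values = np.clip(values, *spec.domain)
            columns[spec.name] = values
        else:
            vals = spec.params["values"]
            probs = np.asarray(spec.params["class_probs"])
            out = np.empty(cfg.n_rows, dtype=object)
            for c in (0, 1):
                mask = y_codes == c
                out[mask] = rng.choice(vals, size=int(mask.sum()), p=probs[c])
            columns[spec.name] = out
        schema.append((spec.name, spec.kind))
    X = pd.DataFrame(columns)
    y = pd.Series(np.asarray(cfg.class_labels)[y_codes], name="label")
    return Dataset(X, y, schema)


def _uniform_composition(name: str, lo: float, hi: float, n_bins: int, n_classes: int) -> AttributeComposition:
    """Class-independent uniform composition: the neutral completion for an
    attribute an expert has no opinion about (it cancels in the posterior)."""
    edges = np.linspace(lo, hi, n_bins + 1)
    chunks = [
        ExpertiseChunk(
            Interval(float(edges[j]), float(edges[j + 1]), j),
            tuple([1.0 / n_bins] * n_classes),
        )
        for j in range(n_bins)
    ]
    return AttributeComposition(name, float(lo), float(hi), chunks)


def _pad_to_schema(
    model: NaiveBayesClassifier, data: Dataset, n_bins: int
) -> NaiveBayesClassifier:
    known = set(model.attribute_names)
    k = model.n_classes
    for name, kind in data.schema:
        if name in known:
            continue
        if kind == CONTINUOUS:
            values = data.X[name].to_numpy(dtype=float)
            lo, hi = float(values.min()), float(values.max())
            if lo == hi:
                lo, hi = lo - 0.5, hi + 0.5
            model.continuous_attrs.append(_uniform_composition(name, lo, hi, n_bins, k))
        else:
            distinct = sorted(pd.unique(data.X[name]), key=repr)
            v = len(distinct)
            model.discrete_attrs.append(
                DiscreteAttributeTable(name, {val: [1.0 / v] * k for val in distinct})
            )
    return model


def generate_expert_pool(
    data: Dataset,
    n_subsets: int = 20,
    top_m: int = 9,
    train_params: dict | None = None,
    seed: int = 0,
    max_training_error: float | None = None,
) -> list[NaiveBayesClassifier]:
    """Simulate a pool of pre-existing experts from one training sample.

    Each of ``n_subsets`` random attribute subsets (random size >= 2) is
    split into two random halves and one classifier is trained per half,
    giving 2 * n_subsets candidates ranked by training error (1 - training
    J); the ``top_m`` are returned, padded to the full schema with
    class-independent uniform compositions so the pool shares a schema.
    """
    if len(data.schema) < 2:
        raise ValueError("need at least two attributes to form subsets")
    if top_m > 2 * n_subsets:
        raise ValueError("top_m cannot exceed 2 * n_subsets")
    train_params = dict(train_params or {})
    n_bins = train_params.get("n_bins", 4)
    rng = np.random.default_rng(seed)
    names = data.attribute_names
    candidates = []
    for s in range(n_subsets):
        size = int(rng.integers(2, len(names) + 1))
        subset = [str(s) for s in rng.choice(names, size=size, replace=False)]
        perm = rng.permutation(len(data))
        halves = (perm[: len(perm) // 2], perm[len(perm) // 2 :])
        for h, idx in enumerate(halves):
            sample = data.subset_rows(idx).subset_attributes(subset)
            if sample.y.nunique() < 2:
                continue
            model = train_naive_bayes(sample, **train_params)
            err = 1.0 - j_score(model, sample)
            model.metadata.update(subset=sorted(subset), half=h, training_error=err)
            candidates.append((err, s, h, model))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    if max_training_error is not None:
        candidates = [c for c in candidates if c[0] <= max_training_error]
    chosen = [c[3] for c in candidates[:top_m]]
    return [_pad_to_schema(m, data, n_bins) for m in chosen]


@dataclass
class PlantedScenario:
    """One true-structure expert among noise experts, plus context data."""

    experts: list[NaiveBayesClassifier]
    context: Dataset
    attribute: str
    descriptor: dict = field(default_factory=dict)


def planted_optimum_scenario(
    seed: int,
    n_context: int = 2000,
    n_experts: int = 9,
    n_noise_attrs: int = 3,
    expert_train_n: int = 250,
    n_bins: int = 4,
    class_sds: tuple[float, float] = (1.6, 0.7),
    prevalence: float = 0.5,
    label_noise: float = 0.35,
) -> PlantedScenario:
    """Build the parameter-recovery test bed.

    The informative attribute is a band-shaped marker: both classes share a
    mean but the positive class is concentrated in a central band
    (per-class spreads ``class_sds``), so the class signal lives in *where*
    the interval boundaries fall, not in a single threshold — the structure
    a chunk-recombination method exists for. Expert 0 is trained on a clean
    draw and is the only pool member carrying the full-strength conditional
    probabilities, but on a crude equal-width slicing that cannot place the
    band edges. The remaining experts simulate degraded related contexts:
    trained on draws whose labels are flipped with probability
    ``label_noise`` and sliced with varied binnings (2-6 intervals,
    alternating equal-frequency/equal-width), they carry only attenuated
    probabilities — but their quantile cuts land near the band edges. No
    single expert is the optimum: the planted optimum is a combination of
    the true expert's strong chunks with the sharper cut structure of the
    others, recoverable on the composite grid. The context set is drawn
    from the true structure.
    """
    attribute = "marker"
    specs = [continuous_spec(attribute, class_sds=class_sds)] + [
        continuous_spec(f"noise_{i}") for i in range(n_noise_attrs)
    ]
    rng = np.random.default_rng(seed)

    def draw(n: int) -> Dataset:
        return generate_dataset(
            CohortConfig(n, prevalence, specs, seed=int(rng.integers(2**31)))
        )

    true_expert = train_naive_bayes(draw(expert_train_n), n_bins=n_bins, binning="equal_width")
    true_expert.metadata.update(role="true_structure")
    experts = [true_expert]
    binnings = ("equal_frequency", "equal_width")
    for i in range(n_experts - 1):
        sample = draw(expert_train_n)
        flip_rng = np.random.default_rng(int(rng.integers(2**31)))
        y = sample.y.to_numpy().copy()
        flips = flip_rng.random(len(y)) < label_noise
        y[flips] = 1 - y[flips]
        sample.y = pd.Series(y, name=sample.y.name)
        noise = train_naive_bayes(
            sample, n_bins=2 + i % 5, binning=binnings[i % 2]
        )
        noise.metadata.update(role="noise", label_noise=label_noise)
        experts.append(noise)
    context = draw(n_context)
    descriptor = {
        "attribute": attribute,
        "true_expert_index": 0,
        "true_boundaries": true_expert.composition(attribute).boundaries.tolist(),
        "class_sds": list(class_sds),
        "prevalence": prevalence,
        "label_noise": label_noise,
    }
    return PlantedScenario(experts, context, attribute, descriptor)
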