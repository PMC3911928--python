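"""Naive Bayesian classifiers built from interval-discretized attributes.

The classifier stores, per continuous attribute, an *attribute composition*:
a contiguous slicing of the attribute's domain into half-open intervals,
each carrying one conditional probability per class (a "chunk of expertise").
Discrete attributes carry a plain value -> per-class probability table.
Prediction multiplies class priors with the per-attribute conditional
probabilities of the interval (or value) each observation falls in, i.e. the
usual naive-Bayes posterior with the independence assumption, computed in
log space with a probability floor so edited models never produce NaNs.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Interval",
    "ExpertiseChunk",
    "AttributeComposition",
    "DiscreteAttributeTable",
    "NaiveBayesClassifier",
    "Dataset",
    "train_naive_bayes",
    "locate_interval",
    "posterior",
    "predict",
    "decompose",
    "assemble",
    "PROB_FLOOR",
]

#: floor applied to every factor of the posterior product so that a chunk
#: probability of exactly zero (possible after external edits) cannot
#: collapse the product to an undefined 0/0.
PROB_FLOOR = 1e-12

CONTINUOUS = "continuous"
DISCRETE = "discrete"


@dataclass(frozen=True)
class Interval:
    """Half-open interval [lower, upper) at position ``rank`` in its slicing."""

    lower: float
    upper: float
    rank: int = 0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(
                f"zero- or negative-width interval [{self.lower}, {self.upper})"
            )
        if self.rank < 0:
            raise ValueError("interval rank must be >= 0")

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class ExpertiseChunk:
    """One interval plus its per-class conditional probabilities.

    For a binary classifier this is the triplet
    ``(interval, p(A in I | c1), p(A in I | c2))`` — the unit of knowledge
    the combination engine recombines across experts.
    """

    interval: Interval
    cond_probs: tuple[float, ...]

    def __post_init__(self) -> None:
        probs = tuple(float(p) for p in self.cond_probs)
        object.__setattr__(self, "cond_probs", probs)
        for p in probs:
            if not (0.0 <= p <= 1.0 + 1e-9):
                raise ValueError(f"conditional probability {p} outside [0, 1]")


@dataclass
class AttributeComposition:
    """One expert's slicing of a continuous attribute's domain.

    Chunks tile ``[domain_lower, domain_upper)`` contiguously; per class the
    chunk probabilities form a distribution over the intervals.
    """

    attribute_name: str
    domain_lower: float
    domain_upper: float
    chunks: list[ExpertiseChunk]

    def __post_init__(self) -> None:
        if not self.chunks:
            raise ValueError(f"composition for {self.attribute_name!r} has no chunks")
        for k in range(len(self.chunks) - 1):
            a, b = self.chunks[k].interval, self.chunks[k + 1].interval
            if a.upper != b.lower:
                raise ValueError(
                    f"chunks of {self.attribute_name!r} do not tile the domain: "
                    f"{a.upper} != {b.lower}"
                )

    @property
    def n_chunks(self) -> int:
        return len(self.chunks)

    @property
    def boundaries(self) -> np.ndarray:
        """All interval boundaries, increasing, length n_chunks + 1."""
        bs = [c.interval.lower for c in self.chunks]
        bs.append(self.chunks[-1].interval.upper)
        return np.asarray(bs, dtype=float)

    def probs_matrix(self) -> np.ndarray:
        """(n_chunks, n_classes) matrix of conditional probabilities."""
        return np.asarray([c.cond_probs for c in self.chunks], dtype=float)

    def renormalized(self) -> "AttributeComposition":
        """Rescale each class column to sum to one (uniform if it sums to 0)."""
        mat = self.probs_matrix()
        sums = mat.sum(axis=0)
        mat = np.where(sums > 0.0, mat / np.where(sums > 0.0, sums, 1.0), 1.0 / len(self.chunks))
        chunks = [
            ExpertiseChunk(c.interval, tuple(mat[k]))
            for k, c in enumerate(self.chunks)
        ]
        return AttributeComposition(self.attribute_name, self.domain_lower, self.domain_upper, chunks)


@dataclass
class DiscreteAttributeTable:
    """Value -> per-class probability table for one discrete attribute."""

    attribute_name: str
    value_probs: dict  # value -> list of per-class probabilities

    def probs_for(self, value, n_classes: int) -> np.ndarray:
        try:
            return np.asarray(self.value_probs[value], dtype=float)
        except KeyError:
            # unseen value: class-independent factor, contributes nothing
            return np.full(n_classes, 1.0 / max(len(self.value_probs), 1))


@dataclass
class Dataset:
    """Tabular sample: observation matrix, labels, and a typed schema."""

    X: pd.DataFrame
    y: pd.Series
    schema: list[tuple[str, str]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.schema]
        if list(self.X.columns) != names:
            raise ValueError("schema names do not match data columns")
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")
        for n, kind in self.schema:
            if kind not in (CONTINUOUS, DISCRETE):
                raise ValueError(f"unknown kind {kind!r} for attribute {n!r}")
        na_rows = self.X.index[self.X.isna().any(axis=1)].tolist()
        na_rows += self.y.index[self.y.isna()].tolist()
        if na_rows:
            raise ValueError(f"missing values in rows {sorted(set(na_rows))[:10]}")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def n_rows(self) -> int:
        return len(self.X)

    @property
    def attribute_names(self) -> list[str]:
        return [n for n, _ in self.schema]

    def kind_of(self, name: str) -> str:
        for n, k in self.schema:
            if n == name:
                return k
        raise KeyError(name)

    def subset_rows(self, idx) -> "Dataset":
        return Dataset(
            self.X.iloc[idx].reset_index(drop=True),
            self.y.iloc[idx].reset_index(drop=True),
            list(self.schema),
        )

    def subset_attributes(self, names: Sequence[str]) -> "Dataset":
        schema = [(n, k) for n, k in self.schema if n in set(names)]
        return Dataset(self.X[[n for n, _ in schema]].copy(), self.y.copy(), schema)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label: str, kinds: Mapping[str, str] | None = None) -> "Dataset":
        """Build a dataset from a data frame with a label column.

        Column kinds default to ``discrete`` for object/boolean columns and
        integer columns with at most 10 distinct values, else ``continuous``;
        override per column via ``kinds``.
        """
        if label not in frame.columns:
            raise ValueError(f"label column {label!r} not found")
        X = frame.drop(columns=[label])
        kinds = dict(kinds or {})
        schema = []
        for col in X.columns:
            if col in kinds:
                kind = kinds[col]
            else:
                s = X[col]
                if s.dtype == object or s.dtype == bool:
                    kind = DISCRETE
                elif pd.api.types.is_integer_dtype(s) and s.nunique() <= 10:
                    kind = DISCRETE
                else:
                    kind = CONTINUOUS
            schema.append((col, kind))
        X = X.copy()
        for n, kind in schema:
            if kind == CONTINUOUS:
                X[n] = X[n].astype(float)
        return cls(X, frame[label].copy(), schema)

    @classmethod
    def from_csv(cls, path, label: str = "label", kinds: Mapping[str, str] | None = None) -> "Dataset":
        return cls.from_frame(pd.read_csv(path), label, kinds)

    def to_csv(self, path, label: str = "label") -> None:
        frame = self.X.copy()
        frame[label] = self.y
        frame.to_csv(path, index=False)


@dataclass
class NaiveBayesClassifier:
    """Class priors plus per-attribute interval/value conditional tables."""

    class_labels: list
    class_priors: list[float]
    continuous_attrs: list[AttributeComposition] = field(default_factory=list)
    discrete_attrs: list[DiscreteAttributeTable] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.class_labels) != len(self.class_priors):
            raise ValueError("one prior per class label required")
        total = float(sum(self.class_priors))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class priors sum to {total}, expected 1")
        names = [c.attribute_name for c in self.continuous_attrs] + [
            d.attribute_name for d in self.discrete_attrs
        ]
        if len(names) != len(set(names)):
            raise ValueError("duplicate attribute names in classifier")
        if len(self.class_labels) > 2:
            warnings.warn(
                "more than two classes: the combination engine is validated "
                "for binary classifiers only",
                stacklevel=2,
            )

    # -- lookup ----------------------------------------------------------

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    @property
    def attribute_names(self) -> list[str]:
        return [c.attribute_name for c in self.continuous_attrs] + [
            d.attribute_name for d in self.discrete_attrs
        ]

    def composition(self, name: str) -> AttributeComposition:
        for c in self.continuous_attrs:
            if c.attribute_name == name:
                return c
        raise KeyError(f"no continuous attribute {name!r}")

    def discrete_table(self, name: str) -> DiscreteAttributeTable:
        for d in self.discrete_attrs:
            if d.attribute_name == name:
                return d
        raise KeyError(f"no discrete attribute {name!r}")

    # -- prediction ------------------------------------------------------

    def log_posterior_frame(self, X: pd.DataFrame) -> np.ndarray:
        """Unnormalized per-class log scores for every row of ``X``."""
        n = len(X)
        scores = np.tile(
            np.log(np.maximum(np.asarray(self.class_priors, float), PROB_FLOOR)),
            (n, 1),
        )
        for comp in self.continuous_attrs:
            if comp.attribute_name not in X.columns:
                raise ValueError(f"attribute {comp.attribute_name!r} missing from data")
            values = X[comp.attribute_name].to_numpy(dtype=float)
            idx = _locate_vector(comp.boundaries, values)
            probs = np.maximum(comp.probs_matrix(), PROB_FLOOR)
            scores += np.log(probs)[idx]
        for table in self.discrete_attrs:
            if table.attribute_name not in X.columns:
                raise ValueError(f"attribute {table.attribute_name!r} missing from data")
            values = X[table.attribute_name]
            probs = np.stack(
                [np.maximum(table.probs_for(v, self.n_classes), PROB_FLOOR) for v in values]
            )
            scores += np.log(probs)
        return scores

    def posterior_frame(self, X: pd.DataFrame) -> np.ndarray:
        """Normalized posterior p(c | x) for every row; rows sum to 1."""
        log_scores = self.log_posterior_frame(X)
        log_scores -= log_scores.max(axis=1, keepdims=True)
        p = np.exp(log_scores)
        return p / p.sum(axis=1, keepdims=True)

    def predict_frame(self, X: pd.DataFrame) -> np.ndarray:
        """Most probable class per row; ties break to the first label."""
        idx = np.argmax(self.log_posterior_frame(X), axis=1)
        return np.asarray(self.class_labels, dtype=object)[idx]

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "class_labels": list(self.class_labels),
            "class_priors": [float(p) for p in self.class_priors],
            "continuous_attrs": [
                {
                    "name": c.attribute_name,
                    "domain": [c.domain_lower, c.domain_upper],
                    "boundaries": c.boundaries.tolist(),
                    "cond_probs": {
                        str(lbl): [float(ch.cond_probs[k]) for ch in c.chunks]
                        for k, lbl in enumerate(self.class_labels)
                    },
                }
                for c in self.continuous_attrs
            ],
            "discrete_attrs": [
                {
                    "name": d.attribute_name,
                    # pairs, not an object: JSON keys are strings and would
                    # break non-string value lookup after a round trip
                    "value_probs": [
                        [v.item() if hasattr(v, "item") else v, [float(p) for p in ps]]
                        for v, ps in d.value_probs.items()
                    ],
                }
                for d in self.discrete_attrs
            ],
            "metadata": self.metadata,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "NaiveBayesClassifier":
        labels = d["class_labels"]
        continuous = []
        for c in d["continuous_attrs"]:
            bs = c["boundaries"]
            chunks = []
            for k in range(len(bs) - 1):
                probs = tuple(c["cond_probs"][str(lbl)][k] for lbl in labels)
                chunks.append(ExpertiseChunk(Interval(bs[k], bs[k + 1], k), probs))
            continuous.append(
                AttributeComposition(c["name"], c["domain"][0], c["domain"][1], chunks)
            )
        discrete = [
            DiscreteAttributeTable(a["name"], {v: list(ps) for v, ps in a["value_probs"]})
            for a in d["discrete_attrs"]
        ]
        return cls(labels, d["class_priors"], continuous, discrete, d.get("metadata", {}))

    @classmethod
    def from_json(cls, path_or_text) -> "NaiveBayesClassifier":
        try:
            with open(path_or_text) as fh:
                d = json.load(fh)
        except (OSError, TypeError):
            d = json.loads(path_or_text)
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# operations


def _locate_vector(boundaries: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Half-open interval index per value, clamped to the boundary intervals."""
    idx = np.searchsorted(boundaries, values, side="right") - 1
    return np.clip(idx, 0, len(boundaries) - 2)


def locate_interval(comp: AttributeComposition, value: float) -> int:
    """Index of the chunk whose half-open interval contains ``value``.

    Values outside the domain (including the global upper bound) clamp to the
    first or last chunk so prediction is total on unseen data.
    """
    return int(_locate_vector(comp.boundaries, np.asarray([value], dtype=float))[0])


def train_naive_bayes(
    data: Dataset,
    n_bins: int = 4,
    binning: str = "equal_frequency",
    smoothing: float = 1.0,
    seed: int = 0,
) -> NaiveBayesClassifier:
    """Fit a naive Bayes classifier with interval-discretized continuous attributes.

    Continuous attributes are sliced into ``n_bins`` intervals (equal-frequency
    by default, robust to skewed clinical measurements; ``equal_width``
    available). Priors and all conditional tables are Laplace-smoothed
    frequency estimates with pseudo-count ``smoothing``, so every per-class
    distribution sums to one and no count is ever zero for smoothing > 0.
    """
    if len(data) == 0:
        raise ValueError("empty dataset")
    labels = sorted(pd.unique(data.y), key=repr)
    labels = [lbl.item() if hasattr(lbl, "item") else lbl for lbl in labels]
    if len(labels) < 2:
        raise ValueError("degenerate labels: need at least two classes")
    if binning not in ("equal_frequency", "equal_width"):
        raise ValueError(f"unknown binning {binning!r}")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")

    y = data.y.to_numpy()
    n = len(y)
    k = len(labels)
    class_index = {lbl: i for i, lbl in enumerate(labels)}
    y_codes = np.asarray([class_index[v] for v in y])
    class_counts = np.bincount(y_codes, minlength=k).astype(float)
    priors = (class_counts + smoothing) / (n + smoothing * k)

    continuous: list[AttributeComposition] = []
    discrete: list[DiscreteAttributeTable] = []
    for name, kind in data.schema:
        col = data.X[name]
        if kind == CONTINUOUS:
            values = col.to_numpy(dtype=float)
            edges = _bin_edges(values, n_bins, binning, name)
            idx = _locate_vector(edges, values)
            m = len(edges) - 1
            counts = np.zeros((m, k))
            for c in range(k):
                counts[:, c] = np.bincount(idx[y_codes == c], minlength=m)
            probs = (counts + smoothing) / (class_counts + smoothing * m)
            chunks = [
                ExpertiseChunk(Interval(edges[j], edges[j + 1], j), tuple(probs[j]))
                for j in range(m)
            ]
            continuous.append(AttributeComposition(name, float(edges[0]), float(edges[-1]), chunks))
        else:
            values = col.to_numpy()
            distinct = pd.unique(values)
            v = len(distinct)
            table = {}
            for val in sorted(distinct, key=repr):
                mask = values == val
                cnt = np.bincount(y_codes[mask], minlength=k).astype(float)
                key = val.item() if hasattr(val, "item") else val
                table[key] = list((cnt + smoothing) / (class_counts + smoothing * v))
            discrete.append(DiscreteAttributeTable(name, table))

    return NaiveBayesClassifier(
        list(labels),
        [float(p) for p in priors],
        continuous,
        discrete,
        metadata={"n_rows": int(n), "n_bins": n_bins, "binning": binning,
                  "smoothing": smoothing, "seed": seed},
    )


def _bin_edges(values: np.ndarray, n_bins: int, binning: str, name: str) -> np.ndarray:
    lo, hi = float(np.min(values)), float(np.max(values))
    if lo == hi:
        warnings.warn(f"attribute {name!r} is constant; using a single unit-width bin")
        return np.asarray([lo - 0.5, lo + 0.5])
    if binning == "equal_width":
        edges = np.linspace(lo, hi, n_bins + 1)
    else:
        edges = np.quantile(values, np.linspace(0.0, 1.0, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) - 1 < n_bins:
        warnings.warn(
            f"attribute {name!r}: only {len(edges) - 1} distinct bins "
            f"(requested {n_bins}); duplicate edges merged"
        )
    if len(edges) < 2:  # pragma: no cover - guarded by the constant case above
        edges = np.asarray([lo - 0.5, hi + 0.5])
    return edges


def posterior(model: NaiveBayesClassifier, x: Mapping) -> np.ndarray:
    """Posterior class probabilities for one observation mapping/series."""
    row = pd.DataFrame([dict(x)])
    return model.posterior_frame(row)[0]


def predict(model: NaiveBayesClassifier, x: Mapping):
    """Most probable class of one observation; ties break to the first label."""
    row = pd.DataFrame([dict(x)])
    return model.predict_frame(row)[0]


def decompose(model: NaiveBayesClassifier) -> dict[str, list[ExpertiseChunk]]:
    """Per-attribute chunks of expertise (discrete attributes yield none)."""
    out: dict[str, list[ExpertiseChunk]] = {
        c.attribute_name: list(c.chunks) for c in model.continuous_attrs
    }
    for d in model.discrete_attrs:
        out[d.attribute_name] = []
    return out


def assemble(
    base: NaiveBayesClassifier,
    replacements: Mapping[str, AttributeComposition],
) -> NaiveBayesClassifier:
    """New classifier equal to ``base`` with the named compositions swapped in.

    Replacement compositions are renormalized per class before insertion so
    the result stays a probability model; ``base`` is left unmodified.
    """
    known = {c.attribute_name for c in base.continuous_attrs}
    for name in replacements:
        if name not in known:
            raise KeyError(f"attribute {name!r} is not a continuous attribute of the base")
    new = copy.deepcopy(base)
    new.continuous_attrs = [
        replacements[c.attribute_name].renormalized()
        if c.attribute_name in replacements
        else c
        for c in new.continuous_attrs
    ]
    return new
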