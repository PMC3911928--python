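"""Ant-colony recombination of expert attribute compositions.

For one continuous attribute, all experts' interval boundaries are merged
into a composite sorted boundary vector (the graph nodes). Between each
pair of consecutive nodes there are N parallel edges, one per expert, each
labelled with the expert's conditional probabilities projected onto that
sub-interval and carrying a pheromone level. An ant walks the nodes in
order, picking one edge per interval with probability proportional to
pheromone^alpha * visibility^beta (visibility = sum of the edge's
conditional probabilities), which yields a candidate attribute composition.
Candidates are scored by the Youden J-index of the base classifier with
that single attribute swapped in, measured on the context data; pheromone
evaporates once per iteration and every ant deposits delta * J on its path.
Composing the best-found composition per attribute, sequentially across
attributes, yields the combined classifier.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bayes import (
    PROB_FLOOR,
    AttributeComposition,
    Dataset,
    ExpertiseChunk,
    Interval,
    NaiveBayesClassifier,
    assemble,
)
from .evaluation import j_score

__all__ = [
    "Edge",
    "AttributeGraph",
    "AntPath",
    "ACOConfig",
    "OptimizationTrace",
    "build_attribute_graph",
    "project_probabilities",
    "transition_probabilities",
    "roulette_select",
    "construct_solution",
    "path_to_composition",
    "evaluate_solution",
    "update_pheromone",
    "optimize_attribute",
    "exhaustive_oracle",
    "combine_classifiers",
]

PHEROMONE_FLOOR = 1e-12
BOUNDARY_RTOL = 1e-9


@dataclass
class Edge:
    """One expert's offer for one composite interval."""

    interval_index: int
    source_expert: int
    cond_probs: np.ndarray
    pheromone: float = 1.0

    def __post_init__(self) -> None:
        self.cond_probs = np.asarray(self.cond_probs, dtype=float)
        if self.pheromone <= 0:
            raise ValueError("pheromone must stay positive")

    @property
    def visibility(self) -> float:
        """Sum of the edge's conditional probabilities (the eta of the walk)."""
        return float(self.cond_probs.sum())


@dataclass
class AttributeGraph:
    """Composite boundary nodes with N parallel edges per interval."""

    attribute_name: str
    boundaries: np.ndarray
    edges: list[list[Edge]]  # edges[j][e]: interval j, expert e
    n_experts: int

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if not np.all(np.diff(self.boundaries) > 0):
            raise ValueError("boundaries must be strictly increasing")
        if len(self.edges) != self.m:
            raise ValueError("one edge bundle per interval required")
        for bundle in self.edges:
            if len(bundle) != self.n_experts:
                raise ValueError("one edge per expert per interval required")

    @property
    def m(self) -> int:
        """Number of composite intervals."""
        return len(self.boundaries) - 1

    def evaporate(self, rho: float) -> None:
        for bundle in self.edges:
            for e in bundle:
                e.pheromone = max((1.0 - rho) * e.pheromone, PHEROMONE_FLOOR)


@dataclass(frozen=True)
class AntPath:
    """One chosen edge (expert index) per composite interval."""

    choices: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "choices", tuple(int(c) for c in self.choices))

    def __len__(self) -> int:
        return len(self.choices)


@dataclass
class ACOConfig:
    """Run parameters of the colony.

    n_iterations is the termination criterion NC, n_ants the colony size NA,
    delta the base pheromone deposit (multiplied by the solution's J-index),
    rho the per-iteration evaporation rate, and alpha/beta the exponents
    balancing pheromone against visibility in the transition rule.
    """

    n_iterations: int = 50
    n_ants: int = 20
    delta: float = 1.0
    rho: float = 0.02
    alpha: float = 2.0
    beta: float = 1.0
    seed: int = 0
    tau0: float = 1.0
    renormalize: bool = True
    projection: str = "proportional"

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [0, 1]")
        if self.n_iterations < 1 or self.n_ants < 1:
            raise ValueError("n_iterations and n_ants must be >= 1")
        if self.tau0 <= 0:
            raise ValueError("tau0 must be positive")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.projection not in ("proportional", "inherit"):
            raise ValueError("projection must be 'proportional' or 'inherit'")


@dataclass
class OptimizationTrace:
    """Best-so-far fitness per iteration plus the winning path/composition."""

    best_so_far: list[float] = field(default_factory=list)
    best_path: AntPath | None = None
    best_composition: AttributeComposition | None = None
    evaluations_count: int = 0

    @property
    def best_j(self) -> float:
        return self.best_so_far[-1] if self.best_so_far else float("-inf")


# ---------------------------------------------------------------------------
# graph construction


def _merged_boundaries(experts, attribute: str) -> np.ndarray:
    values = np.sort(
        np.concatenate([e.composition(attribute).boundaries for e in experts])
    )
    merged = [values[0]]
    for v in values[1:]:
        scale = max(abs(v), abs(merged[-1]), 1.0)
        if v - merged[-1] > BOUNDARY_RTOL * scale:
            merged.append(v)
    return np.asarray(merged)


def project_probabilities(
    source_comp: AttributeComposition,
    sub: Interval,
    projection: str = "proportional",
) -> np.ndarray:
    """Conditional probabilities of a sub-interval under one expert.

    ``proportional`` allocates each original interval's mass uniformly over
    its width (so the sub-interval probabilities of one original interval
    telescope back to its original probability exactly); ``inherit`` copies
    the probability of the original interval containing the sub-interval's
    midpoint unchanged.
    """
    bounds = source_comp.boundaries
    probs = source_comp.probs_matrix()
    if projection == "inherit":
        mid = 0.5 * (sub.lower + sub.upper)
        idx = int(np.clip(np.searchsorted(bounds, mid, side="right") - 1, 0, len(bounds) - 2))
        return probs[idx].copy()
    lo = np.maximum(bounds[:-1], sub.lower)
    hi = np.minimum(bounds[1:], sub.upper)
    overlap = np.maximum(hi - lo, 0.0)
    widths = bounds[1:] - bounds[:-1]
    return (overlap / widths) @ probs


def build_attribute_graph(
    experts: Sequence[NaiveBayesClassifier],
    attribute: str,
    tau0: float = 1.0,
    projection: str = "proportional",
) -> AttributeGraph:
    """Composite boundary vector + N projected, pheromone-bearing edges per interval."""
    if len(experts) < 2:
        raise ValueError("need at least two experts to combine")
    for e in experts:
        if e.n_classes != 2:
            raise ValueError("combination engine is validated for binary classifiers")
        e.composition(attribute)  # raises if missing or discrete
    boundaries = _merged_boundaries(experts, attribute)
    # experts trained on different samples span different ranges; widen each
    # expert's outermost intervals to the composite span (the clamping
    # convention of prediction) so every expert tiles the whole domain and
    # single-expert paths conserve per-class mass exactly
    comps = [
        _widened(e.composition(attribute), float(boundaries[0]), float(boundaries[-1]))
        for e in experts
    ]
    edges = []
    for j in range(len(boundaries) - 1):
        sub = Interval(float(boundaries[j]), float(boundaries[j + 1]), j)
        bundle = [
            Edge(j, k, project_probabilities(comp, sub, projection), tau0)
            for k, comp in enumerate(comps)
        ]
        edges.append(bundle)
    return AttributeGraph(attribute, boundaries, edges, len(experts))


def _widened(comp: AttributeComposition, lo: float, hi: float) -> AttributeComposition:
    first, last = comp.chunks[0], comp.chunks[-1]
    lo = min(lo, first.interval.lower)
    hi = max(hi, last.interval.upper)
    if lo == first.interval.lower and hi == last.interval.upper:
        return comp
    chunks = list(comp.chunks)
    if len(chunks) == 1:
        chunks[0] = ExpertiseChunk(Interval(lo, hi, 0), first.cond_probs)
    else:
        chunks[0] = ExpertiseChunk(Interval(lo, first.interval.upper, 0), first.cond_probs)
        chunks[-1] = ExpertiseChunk(
            Interval(last.interval.lower, hi, last.interval.rank), last.cond_probs
        )
    return AttributeComposition(comp.attribute_name, lo, hi, chunks)


# ---------------------------------------------------------------------------
# ant walk


def transition_probabilities(
    graph: AttributeGraph, interval_index: int, alpha: float, beta: float
) -> np.ndarray:
    """Edge-choice distribution tau^alpha * eta^beta, normalized per interval."""
    bundle = graph.edges[interval_index]
    tau = np.asarray([e.pheromone for e in bundle])
    eta = np.asarray([e.visibility for e in bundle])
    weights = tau**alpha * eta**beta
    total = weights.sum()
    if total <= 0.0 or not np.isfinite(total):
        return np.full(len(bundle), 1.0 / len(bundle))
    return weights / total


def roulette_select(probs: np.ndarray, rng: np.random.Generator) -> int:
    """Casino-wheel draw: index i with probability probs_i / sum(probs)."""
    probs = np.asarray(probs, dtype=float)
    if (probs < 0).any():
        raise ValueError("negative selection weights")
    total = probs.sum()
    if total <= 0.0:
        return int(rng.integers(len(probs)))
    return int(np.searchsorted(np.cumsum(probs / total), rng.random(), side="right").clip(0, len(probs) - 1))


def construct_solution(
    graph: AttributeGraph, config: ACOConfig, rng: np.random.Generator
) -> AntPath:
    """Walk the nodes in boundary order, choosing one edge per interval."""
    choices = [
        roulette_select(
            transition_probabilities(graph, j, config.alpha, config.beta), rng
        )
        for j in range(graph.m)
    ]
    return AntPath(tuple(choices))


def path_to_composition(
    graph: AttributeGraph, path: AntPath, renormalize: bool = True
) -> AttributeComposition:
    """Candidate attribute composition read off a complete ant path."""
    if len(path) != graph.m:
        raise ValueError(f"incomplete path: {len(path)} choices for {graph.m} intervals")
    chunks = []
    for j, choice in enumerate(path.choices):
        edge = graph.edges[j][choice]
        probs = np.clip(edge.cond_probs, 0.0, 1.0)
        chunks.append(
            ExpertiseChunk(
                Interval(float(graph.boundaries[j]), float(graph.boundaries[j + 1]), j),
                tuple(probs),
            )
        )
    comp = AttributeComposition(
        graph.attribute_name, float(graph.boundaries[0]), float(graph.boundaries[-1]), chunks
    )
    return comp.renormalized() if renormalize else comp


def evaluate_solution(
    base: NaiveBayesClassifier,
    attribute: str,
    comp: AttributeComposition,
    context: Dataset,
) -> float:
    """J-index on the context of the base with one attribute swapped in."""
    return j_score(assemble(base, {attribute: comp}), context)


def update_pheromone(
    graph: AttributeGraph,
    path: AntPath,
    quality: float,
    config: ACOConfig,
    evaporate: bool = True,
) -> None:
    """tau' = (1 - rho) tau everywhere, then + delta * quality on the path.

    The optimizer evaporates once per iteration (before any deposits) and
    then lets every ant of the iteration deposit; pass ``evaporate=False``
    for the follow-up deposits.
    """
    if evaporate:
        graph.evaporate(config.rho)
    for j, choice in enumerate(path.choices):
        edge = graph.edges[j][choice]
        edge.pheromone = max(edge.pheromone + config.delta * quality, PHEROMONE_FLOOR)


# ---------------------------------------------------------------------------
# fast path evaluation
#
# During the optimization of one attribute the composite grid and all other
# attributes are fixed, so the per-row log-score contribution of everything
# except the attribute under construction can be precomputed once. A path
# evaluation then reduces to a (m, 2) probability lookup per row.


class _PathEvaluator:
    def __init__(
        self,
        base: NaiveBayesClassifier,
        graph: AttributeGraph,
        context: Dataset,
        renormalize: bool,
    ):
        self.graph = graph
        self.renormalize = renormalize
        rest = assemble(base, {})
        rest.continuous_attrs = [
            c for c in rest.continuous_attrs if c.attribute_name != graph.attribute_name
        ]
        self.rest_scores = rest.log_posterior_frame(context.X)
        values = context.X[graph.attribute_name].to_numpy(dtype=float)
        idx = np.searchsorted(graph.boundaries, values, side="right") - 1
        self.bin_idx = np.clip(idx, 0, graph.m - 1)
        # P[e, j, c]: expert e's projected probabilities on interval j
        self.P = np.stack(
            [
                np.stack([np.clip(graph.edges[j][e].cond_probs, 0.0, 1.0) for j in range(graph.m)])
                for e in range(graph.n_experts)
            ]
        )
        label_index = {lbl: i for i, lbl in enumerate(base.class_labels)}
        self.y_codes = np.asarray([label_index[v] for v in context.y])
        self.k = base.n_classes
        self.class_totals = np.bincount(self.y_codes, minlength=self.k)
        self.present = self.class_totals > 0

    def j_for_choices(self, choices: Sequence[int]) -> float:
        mat = self.P[np.asarray(choices), np.arange(self.graph.m)]  # (m, k)
        if self.renormalize:
            sums = mat.sum(axis=0)
            mat = np.where(sums > 0.0, mat / np.where(sums > 0.0, sums, 1.0), 1.0 / self.graph.m)
        scores = self.rest_scores + np.log(np.maximum(mat, PROB_FLOOR))[self.bin_idx]
        preds = np.argmax(scores, axis=1)
        hits = np.zeros(self.k)
        np.add.at(hits, self.y_codes[preds == self.y_codes], 1)
        recalls = hits[self.present] / self.class_totals[self.present]
        return float(recalls.mean())


# ---------------------------------------------------------------------------
# optimization


def _attr_rng(seed: int, attr_index: int, iteration: int, ant: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, attr_index, iteration, ant])
    )


def optimize_attribute(
    experts: Sequence[NaiveBayesClassifier],
    base: NaiveBayesClassifier,
    attribute: str,
    context: Dataset,
    config: ACOConfig,
    attr_index: int = 0,
) -> tuple[AttributeComposition, OptimizationTrace]:
    """Run NC iterations of NA ants on one attribute's graph.

    Returns the best-ever composition by context J-index together with the
    optimization trace (best-so-far per iteration, non-decreasing).
    """
    graph = build_attribute_graph(experts, attribute, config.tau0, config.projection)
    evaluator = _PathEvaluator(base, graph, context, config.renormalize)
    trace = OptimizationTrace()
    best_j = float("-inf")
    best_path: AntPath | None = None
    for it in range(config.n_iterations):
        ants = []
        for a in range(config.n_ants):
            rng = _attr_rng(config.seed, attr_index, it, a)
            path = construct_solution(graph, config, rng)
            quality = evaluator.j_for_choices(path.choices)
            trace.evaluations_count += 1
            ants.append((path, quality))
            if quality > best_j:
                best_j, best_path = quality, path
        graph.evaporate(config.rho)
        for path, quality in ants:
            update_pheromone(graph, path, quality, config, evaporate=False)
        trace.best_so_far.append(best_j)
    trace.best_path = best_path
    trace.best_composition = path_to_composition(graph, best_path, config.renormalize)
    return trace.best_composition, trace


def exhaustive_oracle(
    experts: Sequence[NaiveBayesClassifier],
    base: NaiveBayesClassifier,
    attribute: str,
    context: Dataset,
    renormalize: bool = True,
    cap: int = 10_000,
    projection: str = "proportional",
) -> tuple[AttributeComposition, float]:
    """Exact optimum over all N^m paths; ties break to the lexicographically
    first path. Test oracle for the stochastic search."""
    graph = build_attribute_graph(experts, attribute, 1.0, projection)
    n_paths = graph.n_experts**graph.m
    if n_paths > cap:
        raise ValueError(f"{n_paths} paths exceed the enumeration cap {cap}")
    evaluator = _PathEvaluator(base, graph, context, renormalize)
    best_j = float("-inf")
    best_choices: tuple[int, ...] | None = None
    for choices in itertools.product(range(graph.n_experts), repeat=graph.m):
        j = evaluator.j_for_choices(choices)
        if j > best_j:
            best_j, best_choices = j, choices
    comp = path_to_composition(graph, AntPath(best_choices), renormalize)
    return comp, best_j


def combine_classifiers(
    experts: Sequence[NaiveBayesClassifier],
    context: Dataset,
    config: ACOConfig,
    attribute_order: Sequence[str] | None = None,
) -> tuple[NaiveBayesClassifier, dict[str, OptimizationTrace]]:
    """Assemble the composite classifier, one attribute at a time.

    The warm start is the pool member with the highest context J-index; the
    search shapes only conditional structure, so the warm start's class
    priors are kept (under the J-index every class weighs equally, and
    replacing the priors with the context prevalence can only move the
    decision rule away from the balanced-recall optimum on unbalanced
    contexts). Attributes are optimized sequentially in schema order (or
    the order given), each accepted composition carried forward so later
    attributes adapt to earlier choices; an optimized composition is kept
    only if it does not degrade the context J of the incumbent.
    """
    if len(experts) < 2:
        raise ValueError("need at least two experts to combine")
    schemas = {tuple(sorted(e.attribute_names)) for e in experts}
    if len(schemas) != 1:
        raise ValueError("experts must share an attribute schema")
    scores = [j_score(e, context) for e in experts]
    base = assemble(experts[int(np.argmax(scores))], {})  # deep copy of the best
    base.metadata = dict(base.metadata, combined=True, seed=config.seed)

    if attribute_order is None:
        attribute_order = [c.attribute_name for c in base.continuous_attrs]
    traces: dict[str, OptimizationTrace] = {}
    incumbent_j = j_score(base, context)
    for i, attribute in enumerate(attribute_order):
        comp, trace = optimize_attribute(experts, base, attribute, context, config, attr_index=i)
        traces[attribute] = trace
        candidate = assemble(base, {attribute: comp})
        candidate_j = j_score(candidate, context)
        if candidate_j >= incumbent_j:
            base, incumbent_j = candidate, candidate_j
    return base, traces
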