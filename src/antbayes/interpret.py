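"""Reading composite classifiers: chunk rendering, predictor quality, stability.

An attribute whose two class-conditional interval distributions are nearly
identical contributes almost nothing to any prediction — a poor predictor.
An attribute that keeps essentially the same, clearly non-uniform
conditional structure across repeated optimization runs is a good predictor:
its chunks are stable knowledge rather than artifacts of one search run.
Both notions are operationalized here with total-variation distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .aco import _widened, project_probabilities
from .bayes import AttributeComposition, Interval, NaiveBayesClassifier

__all__ = [
    "PredictorReport",
    "uniformity_score",
    "stability_score",
    "predictor_report",
    "render_chunks",
]


@dataclass
class PredictorVerdict:
    attribute: str
    uniformity_score: float
    stability_score: float
    verdict: str  # good | poor | indeterminate

    def __post_init__(self) -> None:
        for s in (self.uniformity_score, self.stability_score):
            if not (0.0 <= s <= 1.0 + 1e-12):
                raise ValueError("scores must lie in [0, 1]")


@dataclass
class PredictorReport:
    verdicts: dict[str, PredictorVerdict]
    s_min: float
    u_min: float

    def to_markdown(self) -> str:
        lines = [
            "| attribute | between-class TV | stability | verdict |",
            "|---|---|---|---|",
        ]
        for name in sorted(self.verdicts):
            v = self.verdicts[name]
            lines.append(
                f"| {name} | {v.uniformity_score:.3f} | {v.stability_score:.3f} | {v.verdict} |"
            )
        return "\n".join(lines)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                name: {
                    "uniformity_score": v.uniformity_score,
                    "stability_score": v.stability_score,
                    "verdict": v.verdict,
                }
                for name, v in self.verdicts.items()
            }
        ).T


def uniformity_score(comp: AttributeComposition) -> float:
    """Total-variation distance between the two class-conditional interval
    distributions: 0 for class-identical (uninformative), 1 for disjoint
    support. Symmetric in the classes and invariant under mass-preserving
    re-slicing."""
    mat = comp.renormalized().probs_matrix()
    if mat.shape[1] != 2:
        raise ValueError("uniformity score is defined for binary classifiers")
    return float(0.5 * np.abs(mat[:, 0] - mat[:, 1]).sum())


def _common_grid(runs: Sequence[AttributeComposition]) -> np.ndarray:
    values = np.sort(np.concatenate([r.boundaries for r in runs]))
    keep = [values[0]]
    for v in values[1:]:
        if v - keep[-1] > 1e-12 * max(abs(v), abs(keep[-1]), 1.0):
            keep.append(v)
    return np.asarray(keep)


def _on_grid(comp: AttributeComposition, grid: np.ndarray) -> np.ndarray:
    # widen to the grid span so narrower-domain runs keep all their mass
    comp = _widened(comp.renormalized(), float(grid[0]), float(grid[-1]))
    rows = [
        project_probabilities(comp, Interval(float(grid[j]), float(grid[j + 1]), j))
        for j in range(len(grid) - 1)
    ]
    return np.asarray(rows)


def stability_score(runs: Sequence[AttributeComposition]) -> float:
    """1 minus the mean pairwise TV distance between the runs' compositions,
    compared on their shared composite interval grid; a single run scores 1
    by convention (and is flagged indeterminate in reports)."""
    if not runs:
        raise ValueError("no runs")
    if len(runs) == 1:
        return 1.0
    grid = _common_grid(runs)
    mats = [_on_grid(r, grid) for r in runs]
    dists = []
    for a, b in combinations(mats, 2):
        per_class = 0.5 * np.abs(a - b).sum(axis=0)
        dists.append(per_class.mean())
    return float(np.clip(1.0 - np.mean(dists), 0.0, 1.0))


def predictor_report(
    runs_per_attribute: Mapping[str, Sequence[AttributeComposition]],
    s_min: float = 0.8,
    u_min: float = 0.2,
) -> PredictorReport:
    """Good = stable and clearly non-uniform; poor = near-uniform in every
    run; everything else (including single runs) is indeterminate."""
    verdicts = {}
    for name, runs in runs_per_attribute.items():
        uniformities = [uniformity_score(r) for r in runs]
        u = float(np.mean(uniformities))
        s = stability_score(runs)
        if len(runs) < 2:
            verdict = "indeterminate"
        elif all(x < u_min for x in uniformities):
            verdict = "poor"
        elif s >= s_min and u >= u_min:
            verdict = "good"
        else:
            verdict = "indeterminate"
        verdicts[name] = PredictorVerdict(name, u, s, verdict)
    return PredictorReport(verdicts, s_min, u_min)


def render_chunks(model: NaiveBayesClassifier) -> str:
    """One sentence per chunk, in attribute then interval order.

    Reads like: the conditional probability of a value of AGE to be in the
    interval [29.0, 44.5) is 0.35 when the class is 0 and 0.12 when the
    class is 1.
    """
    lines = []
    for comp in model.continuous_attrs:
        for chunk in comp.chunks:
            parts = " and ".join(
                f"{p:.4f} when the class is {lbl}"
                for p, lbl in zip(chunk.cond_probs, model.class_labels)
            )
            lines.append(
                f"the conditional probability of a value of {comp.attribute_name} "
                f"to be in the interval [{chunk.interval.lower:g}, "
                f"{chunk.interval.upper:g}) is {parts}."
            )
    return "\n".join(lines)
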