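"""Strict and loose accuracy for individual readers and aggregated groups.

Strict accuracy (SA): the group's top-ranked response — or the individual
reader's coded answer — equals the gold-standard finding set exactly.  A
partial answer, or a correct answer buried among extra findings, is strictly
wrong.

Loose accuracy (LA): for groups, the gold finding set appears (as an exact
set match) among the top ``k`` ranked responses (default ``k=5``); for
individuals, every gold finding appears among the reader's findings, possibly
alongside incorrect extras.  LA models a crowd-sourced second-opinion list: a
short ranked menu of candidate diagnoses handed to the clinician.  The list
length k is a heuristic, hence configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .aggregate import GroupRanking, top_k
from .model import Annotation, Dataset

__all__ = [
    "MetricSpec",
    "group_sa",
    "group_la",
    "individual_sa",
    "individual_la",
    "individual_outcome",
    "mean_individual_accuracy",
]


@dataclass(frozen=True)
class MetricSpec:
    """Which accuracy metric to compute; ``k`` only matters for LA."""

    metric: str = "SA"
    k: int = 5

    def __post_init__(self):
        if self.metric not in ("SA", "LA"):
            raise ValueError(f"metric must be 'SA' or 'LA', got {self.metric!r}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")


def group_sa(ranking: GroupRanking, gold: Iterable[str]) -> int:
    """1 iff the top-ranked finding set equals the gold set exactly."""
    if not ranking.entries:
        raise ValueError("empty ranking")
    return int(ranking.top.findings == frozenset(gold))


def group_la(ranking: GroupRanking, gold: Iterable[str], k: int = 5) -> int:
    """1 iff the gold set appears among the top-k ranked finding sets."""
    if not ranking.entries:
        raise ValueError("empty ranking")
    return int(frozenset(gold) in top_k(ranking, k))


def individual_sa(annotation: Annotation, gold: Iterable[str]) -> int:
    """1 iff the reader gave only the correct answer (exact set equality)."""
    return int(annotation.findings == frozenset(gold))


def individual_la(annotation: Annotation, gold: Iterable[str]) -> int:
    """1 iff every gold finding is among the reader's findings (extras allowed)."""
    return int(frozenset(gold) <= annotation.findings)


def individual_outcome(annotation: Annotation, gold: Iterable[str], metric: str) -> int:
    if metric == "SA":
        return individual_sa(annotation, gold)
    if metric == "LA":
        return individual_la(annotation, gold)
    raise ValueError(f"metric must be 'SA' or 'LA', got {metric!r}")


def mean_individual_accuracy(dataset: Dataset, case_id: str, metric: str = "SA") -> float:
    """Arithmetic mean of per-reader binary outcomes over a case's readers."""
    gold = dataset.cases[case_id].gold_findings
    outcomes = [
        individual_outcome(a, gold, metric)
        for a in dataset.annotations
        if a.case_id == case_id
    ]
    if not outcomes:
        raise ValueError(f"case {case_id!r} has no annotations")
    return sum(outcomes) / len(outcomes)
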