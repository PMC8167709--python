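"""Voting protocols: pool one group's annotations into a ranked response list.

Three protocols are supported, all voting on the *whole* coded finding set as
an atomic response:

``frequency``
    Plurality voting — each group member contributes weight 1 to their
    response.
``experience``
    Each member contributes their experience weight (ordinal 1-4 by default).
``confidence``
    Each member contributes their stated confidence (ordinal 1-6).

Responses with equal aggregate weight are put in uniformly random order
(a random permutation within each tie group), consuming the caller's
random generator so that replicate streams stay reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .model import Annotation, Dataset, experience_weight, response_key

__all__ = ["PROTOCOLS", "RankedEntry", "GroupRanking", "aggregate", "top_k"]

PROTOCOLS = ("frequency", "experience", "confidence")


@dataclass(frozen=True)
class RankedEntry:
    key: tuple[str, ...]
    findings: frozenset[str]
    weight: float


@dataclass(frozen=True)
class GroupRanking:
    """Distinct candidate responses of one group, ranked by aggregate weight.

    ``entries`` is a total order: ties were already resolved by random
    permutation, recorded in ``tie_record`` as the sizes of the permuted tie
    groups (empty when the weights alone determined the order).
    """

    case_id: str
    protocol: str
    entries: tuple[RankedEntry, ...]
    tie_record: tuple[int, ...] = ()

    @property
    def top(self) -> RankedEntry:
        return self.entries[0]

    def total_weight(self) -> float:
        return sum(e.weight for e in self.entries)


def _member_weight(
    ann: Annotation,
    protocol: str,
    dataset: Dataset | None,
    experience_weights: Mapping[str, float] | None,
) -> float:
    if protocol == "frequency":
        return 1.0
    if protocol == "confidence":
        return float(ann.confidence)
    if protocol == "experience":
        if dataset is None:
            raise ValueError(
                "experience protocol needs the dataset (reader profiles)"
            )
        category = dataset.readers[ann.reader_id].experience_category
        return float(experience_weight(category, experience_weights))
    raise ValueError(f"unknown protocol {protocol!r}; expected one of {PROTOCOLS}")


def aggregate(
    group: Sequence[Annotation],
    protocol: str,
    rng: np.random.Generator,
    dataset: Dataset | None = None,
    experience_weights: Mapping[str, float] | None = None,
) -> GroupRanking:
    """Pool a group's annotations for one case into a :class:`GroupRanking`.

    Parameters
    ----------
    group
        Non-empty annotations, all for the same case.
    protocol
        One of :data:`PROTOCOLS`.
    rng
        Generator used (only) to break ties; owned by the caller so that a
        bootstrap replicate stream is reproducible.
    dataset
        Required for the ``experience`` protocol (source of reader profiles).
    experience_weights
        Optional override of the default 1-4 ordinal experience mapping.
    """
    if len(group) == 0:
        raise ValueError("cannot aggregate an empty group")
    case_ids = {a.case_id for a in group}
    if len(case_ids) > 1:
        raise ValueError(f"group mixes case ids: {sorted(case_ids)}")
    (case_id,) = case_ids

    weights: dict[tuple[str, ...], float] = {}
    findings_of: dict[tuple[str, ...], frozenset[str]] = {}
    for ann in group:
        k = ann.key
        weights[k] = weights.get(k, 0.0) + _member_weight(
            ann, protocol, dataset, experience_weights
        )
        findings_of.setdefault(k, ann.findings)

    # Canonical (lexicographic) key order inside each weight class before the
    # random permutation, so the rng is the only source of order among ties.
    by_weight: dict[float, list[tuple[str, ...]]] = {}
    for k in sorted(weights):
        by_weight.setdefault(weights[k], []).append(k)

    entries: list[RankedEntry] = []
    tie_record: list[int] = []
    for w in sorted(by_weight, reverse=True):
        tied = by_weight[w]
        if len(tied) > 1:
            order = rng.permutation(len(tied))
            tied = [tied[i] for i in order]
            tie_record.append(len(tied))
        entries.extend(RankedEntry(k, findings_of[k], w) for k in tied)

    return GroupRanking(case_id, protocol, tuple(entries), tuple(tie_record))


def top_k(ranking: GroupRanking, k: int) -> list[frozenset[str]]:
    """First ``min(k, #entries)`` finding sets in rank order."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return [e.findings for e in ranking.entries[:k]]
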