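"""Exact average group accuracy by exhaustive enumeration.

For populations small enough to enumerate every size-n reader subset, the
estimand of :mod:`crowdecg.bootstrap` can be computed exactly: average over
all C(readers, n) groups of the probability that the group is (strictly or
loosely) correct, marginalizing the uniform random tie-break analytically.

For one group, let ``w`` be the gold response's aggregate weight, ``a`` the
number of distinct responses with weight strictly above ``w`` and ``g`` the
number tied at ``w`` (including gold).  Under a uniform random permutation of
each tie class the gold response occupies each of ranks ``a..a+g-1`` with
probability ``1/g``, so

* P(strictly correct)        = (a == 0) / g
* P(loosely correct, top k)  = clip((k - a) / g, 0, 1)

and both are 0 when no group member gave the gold response.

This module is deliberately independent of the Monte Carlo implementation
(plain dict arithmetic over ``itertools.combinations``): it exists to serve
as its small-fixture oracle.  It is infeasible at study scale by design.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Mapping

from .metrics import MetricSpec
from .model import Dataset, experience_weight

__all__ = ["exact_group_probability", "exact_average_accuracy"]


def _tie_class_probability(
    weights: Mapping[tuple[str, ...], float],
    gold_key: tuple[str, ...],
    metric_spec: MetricSpec,
) -> float:
    w = weights.get(gold_key)
    if w is None:
        return 0.0
    above = sum(1 for v in weights.values() if v > w)
    tied = sum(1 for v in weights.values() if v == w)
    if metric_spec.metric == "SA":
        return (1.0 / tied) if above == 0 else 0.0
    return min(max((metric_spec.k - above) / tied, 0.0), 1.0)


def exact_group_probability(
    dataset: Dataset,
    case_id: str,
    member_indices: tuple[int, ...],
    protocol: str,
    metric_spec: MetricSpec,
    experience_weights: Mapping[str, float] | None = None,
) -> float:
    """P(correct) for one explicit group, tie-break marginalized."""
    anns = dataset.annotations_for_case(case_id)
    weights: dict[tuple[str, ...], float] = {}
    for i in member_indices:
        a = anns[i]
        if protocol == "frequency":
            w = 1.0
        elif protocol == "confidence":
            w = float(a.confidence)
        elif protocol == "experience":
            w = float(
                experience_weight(
                    dataset.readers[a.reader_id].experience_category,
                    experience_weights,
                )
            )
        else:
            raise ValueError(f"unknown protocol {protocol!r}")
        weights[a.key] = weights.get(a.key, 0.0) + w
    return _tie_class_probability(
        weights, dataset.cases[case_id].gold_key, metric_spec
    )


def exact_average_accuracy(
    dataset: Dataset,
    case_id: str,
    protocol: str,
    metric_spec: MetricSpec,
    group_size: int,
    experience_weights: Mapping[str, float] | None = None,
    max_groups: int = 200_000,
) -> float:
    """Exact mean accuracy over all size-n groups of a case's readers."""
    anns = dataset.annotations_for_case(case_id)
    n = len(anns)
    n_groups = comb(n, group_size)
    if n_groups > max_groups:
        raise ValueError(
            f"{n_groups} groups of size {group_size} from {n} readers exceeds "
            f"the enumeration limit {max_groups}"
        )
    total = 0.0
    for members in combinations(range(n), group_size):
        total += exact_group_probability(
            dataset, case_id, members, protocol, metric_spec, experience_weights
        )
    return total / n_groups
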