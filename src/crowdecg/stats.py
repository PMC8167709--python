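"""Inferential comparisons: group vs individual accuracy, and correlations
of reader accuracy with confidence and experience.

The group side of the comparison is the sample of bootstrap-cycle average
accuracies; the individual side is either a scalar baseline or the sample of
per-reader binary outcomes.  Two-sided t-tests at alpha = 0.05 by default
(Welch's unequal-variance form for the two-sample case).  No multiplicity
correction is applied across cases.

Correlations are Pearson's rho between per-reader mean accuracy (each reader
averaged over their assigned cases) and per-reader mean confidence, or the
reader's ordinal experience weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import UndefinedCorrelationError
from .metrics import individual_outcome
from .model import Dataset, experience_weight

__all__ = [
    "ComparisonResult",
    "compare_group_vs_individual",
    "reader_summary",
    "accuracy_confidence_correlation",
    "accuracy_experience_correlation",
]


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    p_value: float
    estimate_difference: float  # group minus individual, percentage points
    significant: bool
    alpha: float
    n_group: int
    n_individual: int
    degenerate: bool = False  # zero variance on both sides: no test possible


def compare_group_vs_individual(
    cycle_averages: Sequence[float],
    individual: float | Sequence[float],
    alpha: float = 0.05,
) -> ComparisonResult:
    """Two-tailed t-test of group cycle-average accuracy vs the individual
    baseline.

    ``individual`` may be a scalar mean (one-sample test) or the per-reader
    binary outcomes (Welch two-sample test).  The difference is reported in
    percentage points (group minus individual).
    """
    g = np.asarray(cycle_averages, dtype=float)
    if g.size < 2:
        raise ValueError("need at least 2 cycle averages")
    scalar = np.isscalar(individual) or np.asarray(individual).ndim == 0
    if scalar:
        base = float(individual)
        diff = (g.mean() - base) * 100.0
        if g.std(ddof=1) == 0.0:
            return ComparisonResult(
                float("nan"), 1.0, diff, False, alpha, g.size, 1, degenerate=True
            )
        t, p = sps.ttest_1samp(g, base)
        n_ind = 1
    else:
        ind = np.asarray(individual, dtype=float)
        if ind.size < 2:
            raise ValueError("need at least 2 individual outcomes")
        diff = (g.mean() - ind.mean()) * 100.0
        if g.std(ddof=1) == 0.0 and ind.std(ddof=1) == 0.0:
            return ComparisonResult(
                float("nan"), 1.0, diff, False, alpha, g.size, ind.size, degenerate=True
            )
        t, p = sps.ttest_ind(g, ind, equal_var=False)
        n_ind = ind.size
    return ComparisonResult(
        float(t), float(p), float(diff), bool(p < alpha), alpha, g.size, n_ind
    )


def reader_summary(
    dataset: Dataset,
    metric: str = "SA",
    experience_weights: Mapping[str, float] | None = None,
):
    """Per-reader mean accuracy, mean confidence and experience weight."""
    import pandas as pd

    rows = []
    by_reader: dict[str, list] = {}
    for a in dataset.annotations:
        by_reader.setdefault(a.reader_id, []).append(a)
    for reader_id, anns in sorted(by_reader.items()):
        outcomes = [
            individual_outcome(a, dataset.cases[a.case_id].gold_findings, metric)
            for a in anns
        ]
        rows.append(
            {
                "reader_id": reader_id,
                "n_cases": len(anns),
                "accuracy": float(np.mean(outcomes)),
                "mean_confidence": float(np.mean([a.confidence for a in anns])),
                "experience_weight": float(
                    experience_weight(
                        dataset.readers[reader_id].experience_category,
                        experience_weights,
                    )
                ),
            }
        )
    return pd.DataFrame(rows)


def _pearson(x: np.ndarray, y: np.ndarray, what: str) -> tuple[float, float]:
    if len(x) < 3:
        raise ValueError("need at least 3 readers for a correlation")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise UndefinedCorrelationError(
            f"{what}: zero variance on one axis, correlation undefined"
        )
    r = sps.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def accuracy_confidence_correlation(
    dataset: Dataset, metric: str = "SA"
) -> tuple[float, float]:
    """Pearson rho (and two-tailed p) between per-reader mean accuracy and
    per-reader mean confidence."""
    df = reader_summary(dataset, metric)
    return _pearson(
        df["accuracy"].to_numpy(),
        df["mean_confidence"].to_numpy(),
        "accuracy vs confidence",
    )


def accuracy_experience_correlation(
    dataset: Dataset,
    metric: str = "SA",
    experience_weights: Mapping[str, float] | None = None,
) -> tuple[float, float]:
    """Pearson rho (and two-tailed p) between per-reader mean accuracy and
    experience weight."""
    df = reader_summary(dataset, metric, experience_weights)
    return _pearson(
        df["accuracy"].to_numpy(),
        df["experience_weight"].to_numpy(),
        "accuracy vs experience",
    )
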