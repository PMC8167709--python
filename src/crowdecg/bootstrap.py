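"""Nested resampling of group accuracy across group sizes.

The estimand, for one case, protocol, metric and group size ``n``, is the
average accuracy of a uniformly random ``n``-member group of that case's
readers (tie-breaks marginalized).  Exact computation over all C(readers, n)
groups is infeasible at study scale, so the procedure is Monte Carlo with a
bootstrap layer for uncertainty:

1. For each of ``n_cycles`` cycles, sample ``n_samples`` groups uniformly at
   random (readers drawn without replacement within a group), aggregate each
   group under every protocol, score SA and LA, and average across the
   ``n_samples`` groups — one *cycle average* per cell.
2. Resample the ``n_cycles`` cycle averages with replacement ``n_boots``
   times; report the mean of the bootstrap means, their standard deviation
   and median, and a percentile confidence interval.

Defaults are 500 cycles x 500 samples x 500 bootstrap resamples over group
sizes 3..30.

Implementation notes
--------------------
* One sampled group is shared by all protocols and both metrics (the group's
  weight tables differ, not its membership), and within one cycle the groups
  of different sizes are nested prefixes of a single random reader
  permutation.  Every size's marginal distribution is exactly uniform over
  size-n subsets; sharing randomness across sizes and protocols is a
  common-random-numbers variance-reduction device that also makes the
  degeneracy identity (equal weights => identical curves) hold exactly.
* Ties are broken by adding U(0,1) jitter to the integer-valued aggregate
  weights, which is equivalent to a uniform random permutation within each
  tie group.  The sweep therefore requires integer voting weights (the
  default ordinal scales are integers); :func:`crowdecg.aggregate.aggregate`
  handles arbitrary positive weights for single groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .aggregate import PROTOCOLS, aggregate
from .errors import ConfigError
from .metrics import MetricSpec, group_la, group_sa
from .model import Dataset, experience_weight

__all__ = [
    "BootstrapConfig",
    "AccuracyEstimate",
    "sample_group",
    "cycle_average_accuracy",
    "estimate",
    "sweep",
    "estimates_table",
]

logger = logging.getLogger(__name__)

DEFAULT_GROUP_SIZES = tuple(range(3, 31))

# target number of random matrix elements per kernel chunk (memory knob)
_CHUNK_ELEMENTS = 4_000_000


@dataclass(frozen=True)
class BootstrapConfig:
    n_cycles: int = 500
    n_samples: int = 500
    n_boots: int = 500
    group_sizes: tuple[int, ...] = DEFAULT_GROUP_SIZES
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self):
        for name in ("n_cycles", "n_samples", "n_boots"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        sizes = tuple(sorted(set(int(s) for s in self.group_sizes)))
        if not sizes:
            raise ConfigError("group_sizes must be non-empty")
        if sizes[0] < 3:
            raise ConfigError(
                f"group sizes must be >= 3 (the minimal majority vote), got {sizes[0]}"
            )
        object.__setattr__(self, "group_sizes", sizes)
        if not 0 < self.ci_level < 1:
            raise ConfigError(f"ci_level must be in (0,1), got {self.ci_level}")


@dataclass(frozen=True)
class AccuracyEstimate:
    """Bootstrap summary of average group accuracy for one analysis cell."""

    case_id: str
    protocol: str
    metric: str
    k: int | None
    group_size: int
    mean: float
    sd: float
    median: float
    ci_low: float
    ci_high: float


# ---------------------------------------------------------------------------
# readable reference path (single groups / single cycles)
# ---------------------------------------------------------------------------

def sample_group(readers_of_case: Sequence[str], n: int, rng: np.random.Generator) -> list[str]:
    """``n`` distinct reader ids, uniform over size-n subsets."""
    if n > len(readers_of_case):
        raise ValueError(
            f"cannot sample a group of {n} from {len(readers_of_case)} readers"
        )
    idx = rng.choice(len(readers_of_case), size=n, replace=False)
    return [readers_of_case[i] for i in idx]


def cycle_average_accuracy(
    dataset: Dataset,
    case_id: str,
    protocol: str,
    metric_spec: MetricSpec,
    group_size: int,
    n_samples: int,
    rng: np.random.Generator,
    experience_weights: Mapping[str, float] | None = None,
) -> float:
    """Mean binary group outcome over ``n_samples`` independently sampled groups.

    This is the plain (unvectorized) form of one bootstrap cycle; the sweep
    uses an equivalent vectorized kernel.
    """
    anns = dataset.annotations_for_case(case_id)
    if group_size > len(anns):
        raise ValueError(
            f"case {case_id!r}: group size {group_size} exceeds its "
            f"{len(anns)} readers"
        )
    gold = dataset.cases[case_id].gold_findings
    total = 0
    for _ in range(n_samples):
        idx = rng.choice(len(anns), size=group_size, replace=False)
        ranking = aggregate(
            [anns[i] for i in idx], protocol, rng, dataset, experience_weights
        )
        if metric_spec.metric == "SA":
            total += group_sa(ranking, gold)
        else:
            total += group_la(ranking, gold, metric_spec.k)
    return total / n_samples


# ---------------------------------------------------------------------------
# vectorized kernel
# ---------------------------------------------------------------------------

def _case_arrays(
    dataset: Dataset,
    case_id: str,
    experience_weights: Mapping[str, float] | None,
) -> tuple[np.ndarray, dict[str, np.ndarray], int, int]:
    """Encode a case's annotations as (response index, per-protocol weights).

    Returns ``(key_idx, weights_by_protocol, n_keys, gold_idx)`` where
    ``gold_idx`` is -1 when no reader ever gave the gold response.
    """
    anns = dataset.annotations_for_case(case_id)
    if not anns:
        raise ValueError(f"case {case_id!r} has no annotations")
    keys = sorted({a.key for a in anns})
    key_to_idx = {k: i for i, k in enumerate(keys)}
    key_idx = np.array([key_to_idx[a.key] for a in anns], dtype=np.int64)
    w_exp = np.array(
        [
            experience_weight(
                dataset.readers[a.reader_id].experience_category, experience_weights
            )
            for a in anns
        ],
        dtype=np.float64,
    )
    w_conf = np.array([a.confidence for a in anns], dtype=np.float64)
    for name, w in (("experience", w_exp), ("confidence", w_conf)):
        if not np.allclose(w, np.round(w)):
            raise ConfigError(
                f"sweep requires integer-valued {name} weights for exact "
                "tie-breaking; use aggregate() directly for float weights"
            )
    weights = {
        "frequency": np.ones(len(anns)),
        "experience": w_exp,
        "confidence": w_conf,
    }
    gold_idx = key_to_idx.get(dataset.cases[case_id].gold_key, -1)
    return key_idx, weights, len(keys), gold_idx


def _permutation_prefix(rng: np.random.Generator, m: int, n: int, width: int) -> np.ndarray:
    """First ``width`` entries of ``m`` independent uniform permutations of n."""
    u = rng.random((m, n))
    if width >= n:
        return np.argsort(u, axis=1)
    part = np.argpartition(u, width - 1, axis=1)[:, :width]
    order = np.argsort(np.take_along_axis(u, part, axis=1), axis=1)
    return np.take_along_axis(part, order, axis=1)


def _simulate_cycle_means(
    key_idx: np.ndarray,
    weights: Mapping[str, np.ndarray],
    n_keys: int,
    gold_idx: int,
    protocols: Sequence[str],
    sizes: Sequence[int],
    ks: Sequence[int],
    n_cycles: int,
    n_samples: int,
    rng: np.random.Generator,
) -> dict[tuple[str, str, int | None, int], np.ndarray]:
    """Cycle-average accuracy arrays per (protocol, metric, k, size) cell.

    ``ks`` are the LA list lengths requested; SA is always computed.
    """
    n = len(key_idx)
    sizes = sorted(set(sizes))
    if sizes[-1] > n:
        raise ValueError(f"group size {sizes[-1]} exceeds population {n}")
    out = {
        (p, met, k, s): np.empty(n_cycles)
        for p in protocols
        for met, k in [("SA", None)] + [("LA", k) for k in sorted(set(ks))]
        for s in sizes
    }
    max_size = sizes[-1]
    size_set = set(sizes)
    chunk = max(1, min(n_cycles, _CHUNK_ELEMENTS // max(1, n_samples * n)))
    done = 0
    while done < n_cycles:
        cc = min(chunk, n_cycles - done)
        m = cc * n_samples
        perm = _permutation_prefix(rng, m, n, max_size)
        rows = np.arange(m)
        W = {p: np.zeros((m, n_keys)) for p in protocols}
        for s in range(1, max_size + 1):
            members = key_idx[perm[:, s - 1]]
            for p in protocols:
                W[p][rows, members] += weights[p][perm[:, s - 1]]
            if s not in size_set:
                continue
            # one jitter draw shared by all protocols: equal weight tables
            # then yield identical tie resolutions (degeneracy identity)
            jitter = rng.random((m, n_keys))
            for p in protocols:
                if gold_idx < 0:
                    sa = np.zeros(m, dtype=bool)
                    higher = None
                    present = None
                else:
                    Wp = W[p]
                    Wj = Wp + jitter
                    gv = Wj[:, gold_idx][:, None]
                    present = Wp[:, gold_idx] > 0
                    # absent responses have Wj < 1 <= gold's weight when the
                    # gold response is present, so they never outrank it
                    higher = (Wj > gv).sum(axis=1)
                    sa = present & (higher == 0)
                out[(p, "SA", None, s)][done : done + cc] = (
                    sa.reshape(cc, n_samples).mean(axis=1)
                )
                for k in sorted(set(ks)):
                    la = (
                        np.zeros(m, dtype=bool)
                        if gold_idx < 0
                        else present & (higher < k)
                    )
                    out[(p, "LA", k, s)][done : done + cc] = (
                        la.reshape(cc, n_samples).mean(axis=1)
                    )
        done += cc
    return out


def _summarize(
    cycle_means: np.ndarray,
    n_boots: int,
    ci_level: float,
    boot_idx: np.ndarray,
) -> tuple[float, float, float, float, float]:
    boot_means = cycle_means[boot_idx].mean(axis=1)
    lo_q = 100 * (1 - ci_level) / 2
    lo, hi = np.percentile(boot_means, [lo_q, 100 - lo_q])
    sd = float(boot_means.std(ddof=1)) if n_boots > 1 else 0.0
    return float(boot_means.mean()), sd, float(np.median(boot_means)), float(lo), float(hi)


# ---------------------------------------------------------------------------
# public estimation API
# ---------------------------------------------------------------------------

def estimate(
    dataset: Dataset,
    case_id: str,
    protocol: str,
    metric_spec: MetricSpec,
    group_size: int,
    config: BootstrapConfig,
    experience_weights: Mapping[str, float] | None = None,
) -> AccuracyEstimate:
    """Bootstrap estimate of average group accuracy for one analysis cell."""
    key_idx, weights, n_keys, gold_idx = _case_arrays(
        dataset, case_id, experience_weights
    )
    ss = np.random.SeedSequence(config.seed)
    kernel_ss, boot_ss = ss.spawn(2)
    cells = _simulate_cycle_means(
        key_idx,
        weights,
        n_keys,
        gold_idx,
        [protocol],
        [group_size],
        [metric_spec.k] if metric_spec.metric == "LA" else [],
        config.n_cycles,
        config.n_samples,
        np.random.default_rng(kernel_ss),
    )
    k = metric_spec.k if metric_spec.metric == "LA" else None
    cycle_means = cells[(protocol, metric_spec.metric, k, group_size)]
    boot_rng = np.random.default_rng(boot_ss)
    boot_idx = boot_rng.integers(0, config.n_cycles, (config.n_boots, config.n_cycles))
    mean, sd, median, lo, hi = _summarize(
        cycle_means, config.n_boots, config.ci_level, boot_idx
    )
    return AccuracyEstimate(
        case_id, protocol, metric_spec.metric, k, group_size, mean, sd, median, lo, hi
    )


def cycle_averages(
    dataset: Dataset,
    case_id: str,
    protocol: str,
    metric_spec: MetricSpec,
    group_size: int,
    config: BootstrapConfig,
    experience_weights: Mapping[str, float] | None = None,
) -> np.ndarray:
    """The raw ``n_cycles`` cycle-average accuracies for one analysis cell
    (the sample the group-vs-individual t-test is run on)."""
    key_idx, weights, n_keys, gold_idx = _case_arrays(
        dataset, case_id, experience_weights
    )
    kernel_ss, _ = np.random.SeedSequence(config.seed).spawn(2)
    cells = _simulate_cycle_means(
        key_idx,
        weights,
        n_keys,
        gold_idx,
        [protocol],
        [group_size],
        [metric_spec.k] if metric_spec.metric == "LA" else [],
        config.n_cycles,
        config.n_samples,
        np.random.default_rng(kernel_ss),
    )
    k = metric_spec.k if metric_spec.metric == "LA" else None
    return cells[(protocol, metric_spec.metric, k, group_size)]


def sweep(
    dataset: Dataset,
    protocols: Sequence[str] = PROTOCOLS,
    metric_specs: Sequence[MetricSpec] = (MetricSpec("SA"), MetricSpec("LA", 5)),
    config: BootstrapConfig = BootstrapConfig(),
    experience_weights: Mapping[str, float] | None = None,
) -> list[AccuracyEstimate]:
    """Full factorial sweep: cases x protocols x metrics x group sizes.

    Cases with fewer readers than a requested group size are truncated to
    their feasible sizes with a logged warning.
    """
    for p in protocols:
        if p not in PROTOCOLS:
            raise ConfigError(f"unknown protocol {p!r}")
    ks = sorted({ms.k for ms in metric_specs if ms.metric == "LA"})
    results: list[AccuracyEstimate] = []
    master = np.random.SeedSequence(config.seed)
    case_ids = sorted(dataset.cases)
    seeds = master.spawn(2 * len(case_ids))
    for ci, case_id in enumerate(case_ids):
        kernel_ss, boot_ss = seeds[2 * ci], seeds[2 * ci + 1]
        key_idx, weights, n_keys, gold_idx = _case_arrays(
            dataset, case_id, experience_weights
        )
        n_readers = len(key_idx)
        sizes = [s for s in config.group_sizes if s <= n_readers]
        if len(sizes) < len(config.group_sizes):
            logger.warning(
                "case %s: only %d readers; truncating group sizes to <= %d",
                case_id,
                n_readers,
                n_readers,
            )
        if not sizes or not protocols:
            continue
        cells = _simulate_cycle_means(
            key_idx,
            weights,
            n_keys,
            gold_idx,
            list(protocols),
            sizes,
            ks,
            config.n_cycles,
            config.n_samples,
            np.random.default_rng(kernel_ss),
        )
        # one bootstrap resampling plan per (case, size), shared across
        # protocols and metrics: identical cycle means then give identical
        # estimates, and bootstrap noise cancels in within-case contrasts
        boot_rng = np.random.default_rng(boot_ss)
        boot_by_size = {
            s: boot_rng.integers(0, config.n_cycles, (config.n_boots, config.n_cycles))
            for s in sizes
        }
        for protocol in protocols:
            for ms in metric_specs:
                k = ms.k if ms.metric == "LA" else None
                for s in sizes:
                    mean, sd, median, lo, hi = _summarize(
                        cells[(protocol, ms.metric, k, s)],
                        config.n_boots,
                        config.ci_level,
                        boot_by_size[s],
                    )
                    results.append(
                        AccuracyEstimate(
                            case_id, protocol, ms.metric, k, s, mean, sd, median, lo, hi
                        )
                    )
    return results


def estimates_table(estimates: Iterable[AccuracyEstimate]):
    """Long-format table of sweep results (the data behind the accuracy-vs-
    group-size curves)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "case_id": e.case_id,
                "protocol": e.protocol,
                "metric": e.metric,
                "k": e.k,
                "group_size": e.group_size,
                "mean": e.mean,
                "sd": e.sd,
                "median": e.median,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
            }
            for e in estimates
        ]
    )
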