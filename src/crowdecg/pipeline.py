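"""End-to-end orchestration: generate or load a dataset, sweep group
accuracy, run the statistical comparisons, and write the report tables.

Outputs of a full run (all plain CSV/JSON, regenerable from the manifest):

``curves.csv``
    Long-format accuracy-vs-group-size table per case, protocol and metric.
``comparison.csv``
    Per-case t-tests of group accuracy (at the largest group size) against
    the individual-reader baseline.
``correlations.csv``
    Pearson correlations of per-reader accuracy with confidence and with
    experience.
``difficulty_summary.csv``
    Individual vs largest-group accuracy stratified by case difficulty.
``nonexpert_curves.csv`` / ``expert_baseline.csv`` / ``nonexpert_average.csv``
    Optional expert-split analysis: sweep over the non-expert crowd against
    the individual expert baseline, per case and averaged across cases.
``manifest.json``
    Config, seed and library versions (no timestamps, so a re-run with the
    same config is byte-identical).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregate import PROTOCOLS
from .bootstrap import (
    AccuracyEstimate,
    BootstrapConfig,
    cycle_averages,
    estimates_table,
    sweep,
)
from .errors import ConfigError
from .metrics import MetricSpec, individual_outcome, mean_individual_accuracy
from .model import Dataset, load_dataset
from .simulate import SimulationConfig, default_study_config, generate, preset
from .stats import (
    accuracy_confidence_correlation,
    accuracy_experience_correlation,
    compare_group_vs_individual,
)

__all__ = ["RunConfig", "run", "split_by_expertise", "DEFAULT_EXPERT_CATEGORIES"]

logger = logging.getLogger(__name__)

DEFAULT_EXPERT_CATEGORIES = frozenset({"resident_cardiology"})

_FLOAT_FORMAT = "%.10g"


@dataclass(frozen=True)
class RunConfig:
    """One full analysis run.  Exactly one input source: either the two
    dataset CSV paths or a simulation preset name ('default' for the
    ten-case study configuration, or a regime name)."""

    output_dir: str
    case_table: str | None = None
    annotation_table: str | None = None
    simulation: str | None = None
    n_readers: int = 160
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    protocols: tuple[str, ...] = PROTOCOLS
    k: int = 5
    seed: int = 0
    expert_split: bool = True

    def __post_init__(self):
        from_files = self.case_table is not None and self.annotation_table is not None
        if from_files == (self.simulation is not None):
            raise ConfigError(
                "exactly one input source required: either case_table + "
                "annotation_table, or a simulation preset"
            )

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        boot = BootstrapConfig(**doc.pop("bootstrap", {}))
        protocols = tuple(doc.pop("protocols", PROTOCOLS))
        return RunConfig(bootstrap=boot, protocols=protocols, **doc)


def split_by_expertise(
    dataset: Dataset,
    expert_categories: frozenset[str] | set[str] = DEFAULT_EXPERT_CATEGORIES,
) -> tuple[Dataset, Dataset]:
    """Partition into (expert, non-expert) datasets by reader category.

    The partitions are not re-validated: the expert slice is typically a few
    percent of readers and is used only for individual baselines, never for
    group sweeps.
    """
    expert, crowd = Dataset(), Dataset()
    for part in (expert, crowd):
        part.cases = dict(dataset.cases)
    for rid, profile in dataset.readers.items():
        target = expert if profile.experience_category in expert_categories else crowd
        target.readers[rid] = profile
    for a in dataset.annotations:
        target = expert if a.reader_id in expert.readers else crowd
        target.annotations.append(a)
    return expert, crowd


def _resolve_dataset(config: RunConfig) -> tuple[Dataset, dict]:
    if config.simulation is not None:
        if config.simulation == "default":
            sim = default_study_config(n_readers=config.n_readers, seed=config.seed)
        else:
            sim = preset(config.simulation, n_readers=config.n_readers, seed=config.seed)
        return generate(sim), {"simulation": config.simulation, "n_readers": config.n_readers}
    ds = load_dataset(config.case_table, config.annotation_table)
    return ds, {
        "case_table": str(config.case_table),
        "annotation_table": str(config.annotation_table),
    }


def _metric_specs(k: int) -> tuple[MetricSpec, MetricSpec]:
    return (MetricSpec("SA"), MetricSpec("LA", k))


def _curve_table(estimates: Sequence[AccuracyEstimate]) -> pd.DataFrame:
    return estimates_table(estimates).sort_values(
        ["case_id", "protocol", "metric", "group_size"], kind="stable"
    ).reset_index(drop=True)


def _comparison_table(
    dataset: Dataset, config: RunConfig, curve: pd.DataFrame
) -> pd.DataFrame:
    """Group (largest feasible size) vs individual t-test per case/protocol/metric."""
    rows = []
    for case_id in sorted(dataset.cases):
        gold = dataset.cases[case_id].gold_findings
        anns = dataset.annotations_for_case(case_id)
        sizes = [s for s in config.bootstrap.group_sizes if s <= len(anns)]
        if not sizes:
            continue
        top_size = sizes[-1]
        for protocol in config.protocols:
            for ms in _metric_specs(config.k):
                ind = np.array(
                    [individual_outcome(a, gold, ms.metric) for a in anns], dtype=float
                )
                cyc = cycle_averages(
                    dataset, case_id, protocol, ms, top_size, config.bootstrap
                )
                res = compare_group_vs_individual(cyc, ind)
                rows.append(
                    {
                        "case_id": case_id,
                        "protocol": protocol,
                        "metric": ms.metric,
                        "group_size": top_size,
                        "group_mean": float(np.mean(cyc)),
                        "individual_mean": float(ind.mean()),
                        "difference_points": res.estimate_difference,
                        "t_statistic": res.statistic,
                        "p_value": res.p_value,
                        "significant": res.significant,
                        "degenerate": res.degenerate,
                    }
                )
    return pd.DataFrame(rows)


def _correlation_table(dataset: Dataset) -> pd.DataFrame:
    from .errors import UndefinedCorrelationError

    rows = []
    for metric in ("SA", "LA"):
        for axis, fn in (
            ("confidence", accuracy_confidence_correlation),
            ("experience", accuracy_experience_correlation),
        ):
            try:
                rho, p = fn(dataset, metric)
                rows.append(
                    {"metric": metric, "axis": axis, "rho": rho, "p_value": p,
                     "defined": True}
                )
            except UndefinedCorrelationError:
                rows.append(
                    {"metric": metric, "axis": axis, "rho": float("nan"),
                     "p_value": float("nan"), "defined": False}
                )
    return pd.DataFrame(rows)


def _difficulty_table(
    dataset: Dataset, config: RunConfig, curve: pd.DataFrame
) -> pd.DataFrame:
    """Individual vs largest-group accuracy averaged within difficulty levels."""
    rows = []
    top = curve.loc[curve.groupby(["case_id", "protocol", "metric"])["group_size"].idxmax()]
    for difficulty in ("easy", "medium", "difficult"):
        case_ids = [c for c, rec in dataset.cases.items() if rec.difficulty == difficulty]
        if not case_ids:
            continue
        for protocol in config.protocols:
            for ms in _metric_specs(config.k):
                ind = float(
                    np.mean(
                        [mean_individual_accuracy(dataset, c, ms.metric) for c in case_ids]
                    )
                )
                sel = top[
                    top.case_id.isin(case_ids)
                    & (top.protocol == protocol)
                    & (top.metric == ms.metric)
                ]
                rows.append(
                    {
                        "difficulty": difficulty,
                        "protocol": protocol,
                        "metric": ms.metric,
                        "n_cases": len(case_ids),
                        "individual_mean": ind,
                        "group_mean": float(sel["mean"].mean()),
                    }
                )
    return pd.DataFrame(rows)


def _expert_tables(
    dataset: Dataset, config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame] | None:
    expert, crowd = split_by_expertise(dataset)
    if not expert.annotations:
        logger.warning("no expert readers; skipping expert-split tables")
        return None
    crowd_estimates = sweep(
        crowd, config.protocols, _metric_specs(config.k), config.bootstrap
    )
    crowd_curve = _curve_table(crowd_estimates)
    rows = []
    for case_id in sorted(dataset.cases):
        gold = dataset.cases[case_id].gold_findings
        anns = expert.annotations_for_case(case_id)
        if not anns:
            continue
        for metric in ("SA", "LA"):
            rows.append(
                {
                    "case_id": case_id,
                    "metric": metric,
                    "n_experts": len(anns),
                    "expert_mean": float(
                        np.mean([individual_outcome(a, gold, metric) for a in anns])
                    ),
                }
            )
    expert_baseline = pd.DataFrame(rows)
    average = (
        crowd_curve.groupby(["protocol", "metric", "group_size"], as_index=False)["mean"]
        .mean()
        .rename(columns={"mean": "nonexpert_group_mean"})
    )
    return crowd_curve, expert_baseline, average


def run(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis; returns the artifact paths written."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, source = _resolve_dataset(config)

    estimates = sweep(
        dataset, config.protocols, _metric_specs(config.k), config.bootstrap
    )
    curve = _curve_table(estimates)
    artifacts: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
        artifacts[name] = path

    _write("curves.csv", curve)
    _write("comparison.csv", _comparison_table(dataset, config, curve))
    _write("correlations.csv", _correlation_table(dataset))
    _write("difficulty_summary.csv", _difficulty_table(dataset, config, curve))

    if config.expert_split:
        tables = _expert_tables(dataset, config)
        if tables is not None:
            crowd_curve, expert_baseline, average = tables
            _write("nonexpert_curves.csv", crowd_curve)
            _write("expert_baseline.csv", expert_baseline)
            _write("nonexpert_average.csv", average)

    config_doc = {
        **dataclasses.asdict(config),
        "bootstrap": dataclasses.asdict(config.bootstrap),
    }
    config_doc.pop("output_dir")  # analysis is output-path independent
    manifest = {
        "crowdecg_version": __version__,
        "config": config_doc,
        "input": source,
        "n_cases": len(dataset.cases),
        "n_readers": len(dataset.readers),
        "n_annotations": len(dataset.annotations),
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    artifacts["manifest.json"] = manifest_path
    return artifacts
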