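"""Synthetic reader populations with the statistical structure the analysis
assumes.

The generator emulates a multi-reader interpretation exercise: a pool of
readers with a fixed experience mix, split into questionnaire blocks of
cases; each reader independently draws one coded response per assigned case
from that case's categorical response distribution, and reports an ordinal
confidence whose distribution shifts upward when the drawn response happens
to be the gold standard.  That single shift parameter tunes the
confidence-correctness association; experience is decoupled from correctness
by default and can optionally be linked through a log-odds effect on the
gold-response probability.

Case scenarios come in four qualitative regimes observed in group-accuracy
curves:

``plateau``
    The gold response is each reader's clear modal answer; majority accuracy
    saturates near 100% by group size ~10.
``growth``
    The gold response is modal but contested; accuracy keeps growing through
    group size 30 (no plateau).
``minority_correct``
    A wrong response dominates (gold at ~10%); majority accuracy collapses
    toward 0 as groups grow — the failure mode of majority voting when
    reader errors are correlated.
``multi_finding``
    The gold standard is a composite (two-finding) diagnosis; fragments of
    it are popular wrong answers and the rest of the probability mass is
    fragmented, so the rarely-given complete answer still wins slowly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .model import (
    Annotation,
    CaseRecord,
    Dataset,
    EXPERIENCE_CATEGORIES,
    ReaderProfile,
    experience_weight,
)

__all__ = [
    "ConfidenceModel",
    "CaseScenario",
    "SimulationConfig",
    "generate",
    "preset",
    "default_study_config",
    "with_target_correlation",
    "REGIMES",
]

REGIMES = ("plateau", "growth", "minority_correct", "multi_finding")

#: Experience mix used by default: roughly a quarter senior medical
#: students, half recent graduates, a fifth non-cardiology residents and a
#: few percent cardiology residents — the composition typical of a
#: volunteer student/young-doctor reading pool.
DEFAULT_EXPERIENCE_MIX: Mapping[str, float] = {
    "senior_student": 0.26,
    "recent_graduate": 0.51,
    "resident_other": 0.20,
    "resident_cardiology": 0.03,
}


@dataclass(frozen=True)
class ConfidenceModel:
    """Ordinal 1-6 confidence as a discretized shifted Gaussian.

    ``confidence = clamp(round(N(base_mean, base_sd) + shift * correct), 1, 6)``

    ``correctness_shift = 0`` decouples confidence from correctness; positive
    values create the confidence-accuracy correlation that makes
    confidence-weighted voting outperform plain plurality.
    """

    base_mean: float = 3.0
    base_sd: float = 1.0
    correctness_shift: float = 1.5

    def draw(self, correct: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        raw = rng.normal(self.base_mean, self.base_sd, size=len(correct))
        raw = raw + self.correctness_shift * correct.astype(float)
        return np.clip(np.rint(raw), 1, 6).astype(int)

    @staticmethod
    def shift_for_correlation(
        rho: float,
        gold_probs: Sequence[float],
        base_sd: float = 1.0,
        base_mean: float = 3.0,
    ) -> "ConfidenceModel":
        """Confidence model whose per-reader accuracy-confidence Pearson
        correlation is approximately ``rho``.

        A reader's accuracy over their ``n`` assigned cases has variance
        ``sum p_i (1-p_i) / n^2``; their mean confidence is (ignoring
        rounding and clamping) ``base + shift * accuracy + noise`` with noise
        variance ``base_sd^2 / n``, which gives
        ``shift = rho * (base_sd/sqrt(n)) / (sd_acc * sqrt(1 - rho^2))``.
        """
        if not 0 <= rho < 1:
            raise ConfigError(f"target correlation must be in [0, 1), got {rho}")
        if rho == 0:
            return ConfidenceModel(base_mean, base_sd, 0.0)
        n = len(gold_probs)
        var_acc = sum(p * (1 - p) for p in gold_probs) / n**2
        if var_acc == 0:
            raise ConfigError("degenerate gold probabilities: accuracy has no variance")
        shift = rho * (base_sd / math.sqrt(n)) / (math.sqrt(var_acc) * math.sqrt(1 - rho**2))
        return ConfidenceModel(base_mean, base_sd, shift)


@dataclass(frozen=True)
class CaseScenario:
    """One synthetic case: gold finding set, difficulty, and the categorical
    distribution over candidate coded responses."""

    case_id: str
    gold_findings: frozenset[str]
    difficulty: str
    response_distribution: Mapping[frozenset, float]
    regime: str = "growth"

    def __post_init__(self):
        object.__setattr__(self, "gold_findings", frozenset(self.gold_findings))
        dist = {frozenset(k): float(v) for k, v in self.response_distribution.items()}
        object.__setattr__(self, "response_distribution", dist)
        if self.regime not in REGIMES:
            raise ConfigError(f"unknown regime {self.regime!r}")
        total = sum(dist.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigError(
                f"case {self.case_id!r}: response probabilities sum to {total}, not 1"
            )
        if dist.get(self.gold_findings, 0.0) <= 0.0:
            raise ConfigError(
                f"case {self.case_id!r}: gold response must have nonzero probability"
            )

    @property
    def gold_probability(self) -> float:
        return self.response_distribution[self.gold_findings]


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of a synthetic reader population.

    ``blocks`` mirrors the questionnaire structure: each reader is assigned
    to one block (round-robin) and annotates every case in it.
    """

    n_readers: int
    blocks: tuple[tuple[CaseScenario, ...], ...]
    experience_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXPERIENCE_MIX)
    )
    confidence_model: ConfidenceModel = ConfidenceModel()
    experience_effect: float = 0.0  # log-odds shift of gold prob per weight unit
    seed: int = 0

    def __post_init__(self):
        if self.n_readers < 3:
            raise ConfigError(f"n_readers must be >= 3, got {self.n_readers}")
        if not self.blocks or any(not b for b in self.blocks):
            raise ConfigError("blocks must be non-empty")
        if set(self.experience_mix) != set(EXPERIENCE_CATEGORIES):
            raise ConfigError(
                f"experience_mix must cover exactly {EXPERIENCE_CATEGORIES}"
            )
        total = sum(self.experience_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigError(f"experience_mix sums to {total}, not 1")
        ids = [c.case_id for b in self.blocks for c in b]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate case ids across scenarios")

    @property
    def cases(self) -> tuple[CaseScenario, ...]:
        return tuple(c for b in self.blocks for c in b)


_DIFFICULTY_BASE = {"easy": 2, "medium": 3, "difficult": 4}


def _reader_adjusted_probs(
    scenario: CaseScenario, weight: float, mean_weight: float, effect: float
) -> tuple[list[frozenset], np.ndarray]:
    """Optionally tilt the gold probability on the log-odds scale by the
    reader's (centered) experience weight; other options keep their relative
    proportions."""
    options = sorted(scenario.response_distribution, key=lambda s: tuple(sorted(s)))
    probs = np.array([scenario.response_distribution[o] for o in options])
    if effect != 0.0:
        gi = options.index(scenario.gold_findings)
        p = probs[gi]
        logit = math.log(p / (1 - p)) + effect * (weight - mean_weight)
        p_new = 1 / (1 + math.exp(-logit))
        rest = 1 - probs[gi]
        probs = probs * ((1 - p_new) / rest if rest > 0 else 0.0)
        probs[gi] = p_new
        probs = probs / probs.sum()
    return options, probs


def generate(config: SimulationConfig) -> Dataset:
    """Draw a fully valid :class:`~crowdecg.model.Dataset` from a simulation
    configuration.  Deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    categories = list(EXPERIENCE_CATEGORIES)
    mix = np.array([config.experience_mix[c] for c in categories])
    weights = np.array([experience_weight(c) for c in categories])
    mean_weight = float(weights @ mix)

    ds = Dataset()
    for scenario in config.cases:
        ds.cases[scenario.case_id] = CaseRecord(
            case_id=scenario.case_id,
            gold_findings=scenario.gold_findings,
            difficulty=scenario.difficulty,
        )

    n_blocks = len(config.blocks)
    reader_cat_idx = rng.choice(len(categories), size=config.n_readers, p=mix)
    for i in range(config.n_readers):
        rid = f"r{i:04d}"
        category = categories[reader_cat_idx[i]]
        ds.readers[rid] = ReaderProfile(rid, category)
        block = config.blocks[i % n_blocks]
        w = experience_weight(category)
        for scenario in block:
            options, probs = _reader_adjusted_probs(
                scenario, w, mean_weight, config.experience_effect
            )
            choice = options[rng.choice(len(options), p=probs)]
            correct = np.array([choice == scenario.gold_findings])
            conf = int(config.confidence_model.draw(correct, rng)[0])
            base_diff = _DIFFICULTY_BASE[scenario.difficulty]
            self_diff = int(np.clip(base_diff + rng.integers(-1, 2), 1, 5))
            ds.annotations.append(
                Annotation(
                    reader_id=rid,
                    case_id=scenario.case_id,
                    findings=choice,
                    confidence=conf,
                    self_difficulty=self_diff,
                    used_intuition=bool(rng.random() < 0.5),
                )
            )
    return ds.validate()


# ---------------------------------------------------------------------------
# ready-made scenarios
# ---------------------------------------------------------------------------

def _spread(labels: Sequence[str], total: float) -> dict[frozenset, float]:
    p = total / len(labels)
    return {frozenset([lab]): p for lab in labels}


def _scenario(case_id: str, regime: str, gold: Sequence[str] = ("G",),
              difficulty: str | None = None) -> CaseScenario:
    gold_set = frozenset(gold)
    # every regime keeps a small 'gold plus an extra finding' option: it is
    # loosely but not strictly correct, the way real over-complete reports are
    over = frozenset(gold_set | {"X"})
    if regime == "plateau":
        dist = {gold_set: 0.70, over: 0.05, **_spread(["W1", "W2", "W3"], 0.25)}
        diff = "easy"
    elif regime == "growth":
        # modal but contested gold: keeps climbing through size 30
        dist = {gold_set: 0.45, frozenset(["W1"]): 0.15, over: 0.05,
                **_spread([f"W{i}" for i in range(2, 7)], 0.35)}
        diff = "medium"
    elif regime == "minority_correct":
        # a wrong answer dominates: majority voting buries the gold response
        dist = {gold_set: 0.10, frozenset(["W1"]): 0.55, over: 0.03,
                **_spread([f"W{i}" for i in range(2, 7)], 0.32)}
        diff = "medium"
    elif regime == "multi_finding":
        # composite diagnosis; its fragments are popular wrong answers and
        # the rest of the mass is fragmented across many rare responses
        g = tuple(sorted(gold_set)) if len(gold_set) == 2 else ("A", "B")
        gold_set = frozenset(g)
        over = frozenset(gold_set | {"X"})
        dist = {
            gold_set: 0.08,
            frozenset([g[0]]): 0.07,
            frozenset([g[1]]): 0.06,
            over: 0.04,
            **_spread([f"W{i}" for i in range(1, 12)], 0.75),
        }
        diff = "difficult"
    else:
        raise ConfigError(f"unknown regime {regime!r}")
    return CaseScenario(case_id, gold_set, difficulty or diff, dist, regime)


def preset(regime: str, n_readers: int = 500, seed: int = 0) -> SimulationConfig:
    """Ready-made single-block configuration: five cases of one regime.

    Five cases per reader mirrors the questionnaire-block structure and gives
    per-reader accuracy enough spread for the correlation analyses.
    """
    block = tuple(
        _scenario(f"{regime}{i}", regime, gold=("A", "B") if regime == "multi_finding" else ("G",))
        for i in range(1, 6)
    )
    return SimulationConfig(n_readers=n_readers, blocks=(block,), seed=seed)


def default_study_config(n_readers: int = 160, seed: int = 0) -> SimulationConfig:
    """Ten synthetic ECG-like cases in two questionnaire blocks of five,
    spanning all four regimes and the three difficulty levels."""
    c = _scenario
    block_a = (
        c("ecg01", "plateau", gold=("NORMAL",), difficulty="easy"),
        c("ecg03", "growth", gold=("PERICARDITIS",)),
        c("ecg05", "multi_finding", gold=("AF", "RVH")),
        c("ecg07", "minority_correct", gold=("HYPOTHERMIA",)),
        c("ecg09", "growth", gold=("STEMI",)),
    )
    block_b = (
        c("ecg02", "plateau", gold=("STEMI",), difficulty="easy"),
        c("ecg04", "growth", gold=("PE",)),
        c("ecg06", "multi_finding", gold=("EAR", "AVB_MOBITZ1"), difficulty="difficult"),
        c("ecg08", "plateau", gold=("PSVT",), difficulty="medium"),
        c("ecg10", "minority_correct", gold=("DEXTROCARDIA",)),
    )
    return SimulationConfig(n_readers=n_readers, blocks=(block_a, block_b), seed=seed)


def with_target_correlation(config: SimulationConfig, rho: float) -> SimulationConfig:
    """Copy of ``config`` whose confidence model targets an accuracy-
    confidence correlation of ``rho`` (calibrated to the first block)."""
    gold_probs = [s.gold_probability for s in config.blocks[0]]
    model = ConfidenceModel.shift_for_correlation(
        rho,
        gold_probs,
        config.confidence_model.base_sd,
        config.confidence_model.base_mean,
    )
    return replace(config, confidence_model=model)
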