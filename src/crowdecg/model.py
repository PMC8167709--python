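"""Domain types, validation and tabular I/O for coded multi-reader annotation data.

A *dataset* is the coded outcome of a multi-reader, multi-case interpretation
exercise: every reader writes a free-text interpretation of each assigned case,
and the reports are coded as sets of standardized finding labels (presence /
absence).  A response is therefore an unordered set of finding labels; a case
carries a gold-standard finding set and a three-level difficulty label; a
reader carries a four-level experience category.

The "no pathology" answer is modelled as an explicit finding label (``NORMAL``
by convention) rather than an empty set, so that it can be voted on like any
other response and is distinguishable from a missing answer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "EXPERIENCE_CATEGORIES",
    "DEFAULT_EXPERIENCE_WEIGHTS",
    "DIFFICULTY_LEVELS",
    "FindingVocabulary",
    "ReaderProfile",
    "Annotation",
    "CaseRecord",
    "Dataset",
    "experience_weight",
    "response_key",
    "load_dataset",
    "write_dataset",
    "dataset_to_json",
    "dataset_from_json",
]

#: Four-level reader experience scale, in increasing order of experience.
EXPERIENCE_CATEGORIES = (
    "senior_student",
    "recent_graduate",
    "resident_other",
    "resident_cardiology",
)

#: Default ordinal voting weights: the simplest monotone embedding of the
#: experience scale.  Rankings are invariant to positive rescaling, so only
#: the order matters; the mapping is overridable wherever a weight is used.
DEFAULT_EXPERIENCE_WEIGHTS: Mapping[str, float] = {
    "senior_student": 1,
    "recent_graduate": 2,
    "resident_other": 3,
    "resident_cardiology": 4,
}

DIFFICULTY_LEVELS = ("easy", "medium", "difficult")

CONFIDENCE_MIN, CONFIDENCE_MAX = 1, 6

#: Minimum number of annotations a case needs: the smallest group that can
#: hold a majority vote has three members.
MIN_ANNOTATIONS_PER_CASE = 3


def experience_weight(category: str, mapping: Mapping[str, float] | None = None) -> float:
    """Voting weight for an experience category.

    Parameters
    ----------
    category
        One of :data:`EXPERIENCE_CATEGORIES`.
    mapping
        Optional override of :data:`DEFAULT_EXPERIENCE_WEIGHTS`.  Must assign
        a positive weight to every category it is queried for.
    """
    table = DEFAULT_EXPERIENCE_WEIGHTS if mapping is None else mapping
    try:
        w = table[category]
    except KeyError:
        raise ValueError(
            f"unknown experience category {category!r}; expected one of "
            f"{sorted(table)}"
        ) from None
    if not w > 0:
        raise ValueError(f"experience weight for {category!r} must be > 0, got {w}")
    return w


def response_key(findings: Iterable[str]) -> tuple[str, ...]:
    """Canonical identifier of a coded response.

    Two responses get equal keys iff their present-finding sets are equal;
    the key does not depend on any vocabulary ordering.
    """
    return tuple(sorted(set(findings)))


@dataclass(frozen=True)
class FindingVocabulary:
    """The finding labels in play for one case."""

    case_id: str
    labels: tuple[str, ...]

    def __post_init__(self):
        if not self.labels:
            raise ValueError(f"case {self.case_id!r}: vocabulary must be non-empty")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"case {self.case_id!r}: duplicate finding labels")


@dataclass(frozen=True)
class ReaderProfile:
    reader_id: str
    experience_category: str

    def __post_init__(self):
        if self.experience_category not in EXPERIENCE_CATEGORIES:
            raise ValueError(
                f"reader {self.reader_id!r}: unknown experience category "
                f"{self.experience_category!r}"
            )

    def experience_weight(self, mapping: Mapping[str, float] | None = None) -> float:
        return experience_weight(self.experience_category, mapping)


@dataclass(frozen=True)
class Annotation:
    """One reader's coded answer to one case.

    ``findings`` is the set of finding labels marked present.  A "normal"
    answer is the explicit ``NORMAL``-style label, so ``findings`` is always
    non-empty.
    """

    reader_id: str
    case_id: str
    findings: frozenset[str]
    confidence: int
    self_difficulty: int | None = None
    used_intuition: bool | None = None

    def __post_init__(self):
        object.__setattr__(self, "findings", frozenset(self.findings))

    @property
    def key(self) -> tuple[str, ...]:
        return response_key(self.findings)


@dataclass(frozen=True)
class CaseRecord:
    """A case with its gold-standard finding set and difficulty label."""

    case_id: str
    gold_findings: frozenset[str]
    difficulty: str
    source_difficulty: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "gold_findings", frozenset(self.gold_findings))

    @property
    def gold_key(self) -> tuple[str, ...]:
        return response_key(self.gold_findings)


@dataclass
class Dataset:
    """Cases, readers and annotations of one multi-reader study."""

    cases: dict[str, CaseRecord] = field(default_factory=dict)
    readers: dict[str, ReaderProfile] = field(default_factory=dict)
    annotations: list[Annotation] = field(default_factory=list)

    # -- derived views ----------------------------------------------------

    def annotations_for_case(self, case_id: str) -> list[Annotation]:
        return [a for a in self.annotations if a.case_id == case_id]

    def readers_of_case(self, case_id: str) -> list[str]:
        return [a.reader_id for a in self.annotations if a.case_id == case_id]

    def vocabulary(self, case_id: str) -> FindingVocabulary:
        """Union of gold and observed labels for a case, sorted."""
        labels = set(self.cases[case_id].gold_findings)
        for a in self.annotations:
            if a.case_id == case_id:
                labels |= a.findings
        return FindingVocabulary(case_id, tuple(sorted(labels)))

    # -- validation -------------------------------------------------------

    def validation_failures(self) -> list[str]:
        """All domain-invariant violations, each located by id."""
        failures: list[str] = []
        for c in self.cases.values():
            if not c.gold_findings:
                failures.append(f"case {c.case_id!r}: gold finding set is empty")
            if c.difficulty not in DIFFICULTY_LEVELS:
                failures.append(
                    f"case {c.case_id!r}: difficulty {c.difficulty!r} not in "
                    f"{DIFFICULTY_LEVELS}"
                )
            if c.source_difficulty is not None and not 1 <= c.source_difficulty <= 5:
                failures.append(
                    f"case {c.case_id!r}: source difficulty {c.source_difficulty} "
                    "outside the 1-5 scale"
                )
        seen: set[tuple[str, str]] = set()
        per_case_count: dict[str, int] = {cid: 0 for cid in self.cases}
        for i, a in enumerate(self.annotations):
            where = f"annotation #{i} (reader {a.reader_id!r}, case {a.case_id!r})"
            if a.reader_id not in self.readers:
                failures.append(f"{where}: unknown reader id")
            if a.case_id not in self.cases:
                failures.append(f"{where}: unknown case id")
            else:
                per_case_count[a.case_id] += 1
            if not CONFIDENCE_MIN <= a.confidence <= CONFIDENCE_MAX:
                failures.append(
                    f"{where}: confidence {a.confidence} outside the "
                    f"{CONFIDENCE_MIN}-{CONFIDENCE_MAX} scale"
                )
            if not a.findings:
                failures.append(
                    f"{where}: empty finding set (a normal answer must use an "
                    "explicit label)"
                )
            pair = (a.reader_id, a.case_id)
            if pair in seen:
                failures.append(f"{where}: duplicate (reader, case) annotation")
            seen.add(pair)
        for cid, n in per_case_count.items():
            if n < MIN_ANNOTATIONS_PER_CASE:
                failures.append(
                    f"case {cid!r}: only {n} annotation(s); at least "
                    f"{MIN_ANNOTATIONS_PER_CASE} are required for a majority vote"
                )
        return failures

    def validate(self) -> "Dataset":
        failures = self.validation_failures()
        if failures:
            raise ValidationError(failures)
        return self


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

_CASE_COLUMNS = ("case_id", "difficulty", "gold_findings")
_ANNOTATION_COLUMNS = (
    "reader_id",
    "case_id",
    "experience_category",
    "findings",
    "confidence",
)

_SEP = ";"


def _split_labels(cell: str) -> frozenset[str]:
    return frozenset(s.strip() for s in str(cell).split(_SEP) if s.strip())


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _opt_int(value) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return int(value)


def load_dataset(case_table: str | Path, annotation_table: str | Path) -> Dataset:
    """Read and validate a dataset from its two CSV tables.

    Raises
    ------
    SchemaError
        If a file does not conform to the column schema (message names the
        row and column).
    ValidationError
        If the parsed dataset violates a domain invariant (message lists all
        failures).
    """
    case_path, ann_path = Path(case_table), Path(annotation_table)
    cases_df = pd.read_csv(case_path, dtype=str)
    ann_df = pd.read_csv(ann_path, dtype=str)
    _require_columns(cases_df, _CASE_COLUMNS, case_path)
    _require_columns(ann_df, _ANNOTATION_COLUMNS, ann_path)

    ds = Dataset()
    for i, row in cases_df.iterrows():
        try:
            ds.cases[str(row["case_id"])] = CaseRecord(
                case_id=str(row["case_id"]),
                gold_findings=_split_labels(row["gold_findings"]),
                difficulty=str(row["difficulty"]),
                source_difficulty=_opt_int(row.get("source_difficulty")),
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{case_path}: row {i}: {exc}") from exc

    for i, row in ann_df.iterrows():
        rid = str(row["reader_id"])
        try:
            conf = int(row["confidence"])
        except (TypeError, ValueError):
            raise SchemaError(
                f"{ann_path}: row {i}, column 'confidence': expected an "
                f"integer, got {row['confidence']!r}"
            ) from None
        category = str(row["experience_category"])
        profile = ReaderProfile(rid, category)
        existing = ds.readers.get(rid)
        if existing is not None and existing != profile:
            raise SchemaError(
                f"{ann_path}: row {i}: reader {rid!r} previously declared with "
                f"category {existing.experience_category!r}, now {category!r}"
            )
        ds.readers[rid] = profile
        used = row.get("used_intuition")
        ds.annotations.append(
            Annotation(
                reader_id=rid,
                case_id=str(row["case_id"]),
                findings=_split_labels(row["findings"]),
                confidence=conf,
                self_difficulty=_opt_int(row.get("self_difficulty")),
                used_intuition=None
                if used is None or (isinstance(used, float) and pd.isna(used))
                else str(used).strip().lower() in ("1", "true", "yes"),
            )
        )
    return ds.validate()


def write_dataset(ds: Dataset, case_table: str | Path, annotation_table: str | Path) -> None:
    """Write a dataset to the two-table CSV format (round-trips bitwise on
    the coded fields)."""
    cases = pd.DataFrame(
        [
            {
                "case_id": c.case_id,
                "difficulty": c.difficulty,
                "gold_findings": _SEP.join(sorted(c.gold_findings)),
                "source_difficulty": c.source_difficulty,
            }
            for c in ds.cases.values()
        ]
    )
    anns = pd.DataFrame(
        [
            {
                "reader_id": a.reader_id,
                "case_id": a.case_id,
                "experience_category": ds.readers[a.reader_id].experience_category,
                "findings": _SEP.join(sorted(a.findings)),
                "confidence": a.confidence,
                "self_difficulty": a.self_difficulty,
                "used_intuition": a.used_intuition,
            }
            for a in ds.annotations
        ]
    )
    cases.to_csv(case_table, index=False)
    anns.to_csv(annotation_table, index=False)


# ---------------------------------------------------------------------------
# single-document JSON serialization (schema in crowdecg/schemas/)
# ---------------------------------------------------------------------------

def dataset_to_json(ds: Dataset) -> str:
    doc = {
        "cases": [
            {
                "case_id": c.case_id,
                "difficulty": c.difficulty,
                "gold_findings": sorted(c.gold_findings),
                "source_difficulty": c.source_difficulty,
            }
            for c in ds.cases.values()
        ],
        "readers": [
            {"reader_id": r.reader_id, "experience_category": r.experience_category}
            for r in ds.readers.values()
        ],
        "annotations": [
            {
                "reader_id": a.reader_id,
                "case_id": a.case_id,
                "findings": sorted(a.findings),
                "confidence": a.confidence,
                "self_difficulty": a.self_difficulty,
                "used_intuition": a.used_intuition,
            }
            for a in ds.annotations
        ],
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def dataset_from_json(text: str) -> Dataset:
    doc = json.loads(text)
    ds = Dataset()
    for c in doc["cases"]:
        ds.cases[c["case_id"]] = CaseRecord(
            case_id=c["case_id"],
            gold_findings=frozenset(c["gold_findings"]),
            difficulty=c["difficulty"],
            source_difficulty=c.get("source_difficulty"),
        )
    for r in doc["readers"]:
        ds.readers[r["reader_id"]] = ReaderProfile(
            r["reader_id"], r["experience_category"]
        )
    for a in doc["annotations"]:
        ds.annotations.append(
            Annotation(
                reader_id=a["reader_id"],
                case_id=a["case_id"],
                findings=frozenset(a["findings"]),
                confidence=a["confidence"],
                self_difficulty=a.get("self_difficulty"),
                used_intuition=a.get("used_intuition"),
            )
        )
    return ds.validate()
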