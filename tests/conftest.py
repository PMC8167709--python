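import numpy as np
import pytest

from crowdecg.model import Annotation, CaseRecord, Dataset, ReaderProfile


def make_dataset(cases, annotations):
    """Build a Dataset from compact tuples.

    cases: [(case_id, gold_labels, difficulty)]
    annotations: [(reader_id, case_id, labels, confidence, category)]
    """
    ds = Dataset()
    for case_id, gold, difficulty in cases:
        ds.cases[case_id] = CaseRecord(case_id, frozenset(gold), difficulty)
    for reader_id, case_id, labels, confidence, category in annotations:
        if reader_id not in ds.readers:
            ds.readers[reader_id] = ReaderProfile(reader_id, category)
        ds.annotations.append(
            Annotation(reader_id, case_id, frozenset(labels), confidence)
        )
    return ds


@pytest.fixture
def six_reader_case():
    """Six readers on one case, chosen so that all three protocols have
    non-trivial rankings and frequent ties at group size 3 (20 groups, small
    enough to enumerate exactly)."""
    return make_dataset(
        [("c1", ["G"], "medium")],
        [
            ("r0", "c1", ["G"], 5, "senior_student"),
            ("r1", "c1", ["G"], 2, "recent_graduate"),
            ("r2", "c1", ["W1"], 6, "resident_cardiology"),
            ("r3", "c1", ["W1"], 1, "senior_student"),
            ("r4", "c1", ["W2"], 4, "resident_other"),
            ("r5", "c1", ["G", "W1"], 3, "recent_graduate"),
        ],
    ).validate()


@pytest.fixture
def twelve_reader_case():
    """Twelve readers, 5/12 giving the gold answer; frequency-protocol SA at
    group size 3 is exactly 1/2 (hand enumeration)."""
    specs = ["G"] * 5 + ["W1"] * 2 + ["W2"] * 2 + ["W3"] + ["W4"] * 2
    rng = np.random.default_rng(99)
    return make_dataset(
        [("c", ["G"], "medium")],
        [
            (f"r{i}", "c", [lab], int(rng.integers(1, 7)), "recent_graduate")
            for i, lab in enumerate(specs)
        ],
    ).validate()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
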