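"""Two-class sample labelling from TP53 mutation status.

The screen compares samples *with a functional p53 mutation* (class c1)
against samples *without* one (class c2).  "Functional" here means the
mutation is assumed to abrogate p53 function: nonsense (stop codon),
frameshift and missense changes.  Silent changes — synonymous mutations
and mutations affecting noncoding DNA — are non-functional and are grouped
with wild-type in c2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import MutationRecord

logger = logging.getLogger(__name__)

C1 = "c1"  # functional p53 mutation
C2 = "c2"  # without functional p53 mutation (non-functional mutation or wild-type)

FUNCTIONAL_CLASSES = frozenset({"missense", "nonsense", "frameshift"})
NON_FUNCTIONAL_CLASSES = frozenset({"silent", "synonymous", "noncoding", "none"})


@dataclass(frozen=True)
class ClassLabels:
    """Per-sample assignment to the two comparison classes.

    c1 = "functional p53 mutation", c2 = "without functional p53 mutation".
    Labels are a function of the mutation table only; expression never
    enters the assignment.
    """

    assignments: dict[str, str]
    n_functional_records: dict[str, int]

    def __post_init__(self) -> None:
        bad = {s: c for s, c in self.assignments.items() if c not in (C1, C2)}
        if bad:
            raise ValueError(f"labels must be '{C1}' or '{C2}': {bad}")

    @property
    def c1_samples(self) -> tuple[str, ...]:
        return tuple(s for s, c in self.assignments.items() if c == C1)

    @property
    def c2_samples(self) -> tuple[str, ...]:
        return tuple(s for s, c in self.assignments.items() if c == C2)

    @property
    def class_sizes(self) -> tuple[int, int]:
        return len(self.c1_samples), len(self.c2_samples)

    def mask(self, samples: Sequence[str]) -> np.ndarray:
        """Boolean c1-membership vector in the order of *samples*.

        Raises if any sample has no label — every sample of the paired
        expression dataset must be covered.
        """
        missing = [s for s in samples if s not in self.assignments]
        if missing:
            raise KeyError(f"samples without class label: {missing}")
        return np.array([self.assignments[s] == C1 for s in samples], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        """TSV-ready table sorted by sample id."""
        rows = [
            (s, self.assignments[s], self.n_functional_records.get(s, 0))
            for s in sorted(self.assignments)
        ]
        return pd.DataFrame(rows, columns=["sample_id", "class", "n_functional_records"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ClassLabels":
        return cls(
            assignments=dict(zip(frame["sample_id"], frame["class"])),
            n_functional_records=dict(
                zip(frame["sample_id"], frame["n_functional_records"].astype(int))
            ),
        )


def classify_mutation(record: MutationRecord) -> str:
    """Classify one mutation record as ``functional`` or ``non_functional``.

    missense / nonsense / frameshift → functional; silent / synonymous /
    noncoding / none (wild-type placeholder) → non_functional.
    """
    if record.mutation_class in FUNCTIONAL_CLASSES:
        return "functional"
    assert record.mutation_class in NON_FUNCTIONAL_CLASSES
    return "non_functional"


def assign_labels(
    records: Iterable[MutationRecord], samples: Sequence[str]
) -> ClassLabels:
    """Assign every sample to c1 or c2 from its TP53 records.

    A sample is c1 iff it carries at least one functional TP53 mutation
    ("any-functional" rule; functionality is defined per mutation, so a
    single functional hit places the sample in the functional-mutant
    class).  Samples absent from the mutation table, or present only with
    non-TP53 records, are TP53 wild-type and therefore c2.

    Raises ``ValueError`` if *samples* is empty or either class ends up
    empty (no two-class comparison is possible).
    """
    samples = list(samples)
    if not samples:
        raise ValueError("sample list is empty")
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample identifiers")
    sample_set = set(samples)

    n_functional: dict[str, int] = {s: 0 for s in samples}
    for record in records:
        if record.sample_id not in sample_set:
            logger.warning("mutation record for unknown sample %r ignored", record.sample_id)
            continue
        if not record.is_tp53:
            logger.warning(
                "sample %s: record for gene %s ignored (TP53 status only); "
                "sample treated as TP53 wild-type unless a TP53 record exists",
                record.sample_id,
                record.gene,
            )
            continue
        if classify_mutation(record) == "functional":
            n_functional[record.sample_id] += 1

    assignments = {s: (C1 if n_functional[s] > 0 else C2) for s in samples}
    labels = ClassLabels(assignments=assignments, n_functional_records=n_functional)
    n1, n2 = labels.class_sizes
    if n1 == 0 or n2 == 0:
        raise ValueError(
            f"both classes must be non-empty, got sizes c1={n1}, c2={n2}"
        )
    return labels
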