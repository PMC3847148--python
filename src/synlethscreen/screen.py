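"""Candidate selection and cross-dataset consensus.

A gene is a druggable synthetic-lethality candidate in one dataset when it
is significantly differentially expressed at the chosen level, its
expression is *higher* in the functional-p53-mutant class, and it encodes
a kinase.  Candidates found in at least ``min_datasets`` independent
datasets form the consensus list.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stats import ClassComparisonResult, GeneTestResult, UP_IN_C1


def base_symbol(gene: str) -> str:
    """Strip a probe suffix (``PLK1#2`` → ``PLK1``)."""
    return gene.split("#", 1)[0]


@dataclass(frozen=True)
class CandidateSet:
    """Candidate genes of one dataset run, with the filters that made them."""

    dataset_name: str
    genes: tuple[str, ...]  # base symbols, sorted
    alpha: float
    criteria: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.genes) != sorted(set(self.genes)):
            raise ValueError("candidate genes must be sorted and unique")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": list(self.genes)}).assign(
            dataset=self.dataset_name, alpha=self.alpha
        )


@dataclass(frozen=True)
class ConsensusTable:
    """Genes counted across datasets, filtered at ``min_datasets``.

    ``rows`` hold the filtered consensus; ``union`` is the unfiltered
    complete list (every candidate from any dataset with its count).
    """

    rows: tuple[tuple[str, int, tuple[str, ...]], ...]
    union: tuple[tuple[str, int, tuple[str, ...]], ...]
    min_datasets: int

    def genes(self) -> tuple[str, ...]:
        return tuple(r[0] for r in self.rows)

    def to_frame(self, full: bool = False) -> pd.DataFrame:
        rows = self.union if full else self.rows
        return pd.DataFrame(
            {
                "gene": [r[0] for r in rows],
                "n_datasets": [r[1] for r in rows],
                "datasets": [",".join(r[2]) for r in rows],
            }
        )


def select_candidates(
    results: ClassComparisonResult | Iterable[GeneTestResult],
    kinases: Iterable[str],
    alpha: float = 0.05,
    p_type: str = "parametric",
) -> CandidateSet:
    """Filter one dataset's per-gene results down to candidates.

    A gene is retained iff its selected p-value (``p_type`` one of
    ``parametric``, ``permutation``, ``q``) is at most *alpha*, its
    direction is up-in-c1, and its base symbol is in the kinase list.  A
    gene whose any probe passes is a candidate (probe suffixes collapse to
    the base symbol).
    """
    kinase_set = set(kinases)
    if not kinase_set:
        raise ValueError("kinase set is empty")
    if p_type not in ("parametric", "permutation", "q"):
        raise ValueError(f"p_type must be parametric|permutation|q, got {p_type!r}")
    if isinstance(results, ClassComparisonResult):
        dataset_name = results.dataset_name
        rows: Sequence[GeneTestResult] = results.results
    else:
        rows = tuple(results)
        dataset_name = "dataset"
    attr = {"parametric": "parametric_p", "permutation": "permutation_p", "q": "q_value"}[p_type]
    selected = set()
    for r in rows:
        p = getattr(r, attr)
        if np.isnan(p):
            raise ValueError(
                f"gene {r.gene}: selected p-type {p_type!r} was not computed for this run"
            )
        if p <= alpha and r.direction == UP_IN_C1 and base_symbol(r.gene) in kinase_set:
            selected.add(base_symbol(r.gene))
    return CandidateSet(
        dataset_name=dataset_name,
        genes=tuple(sorted(selected)),
        alpha=alpha,
        criteria={"direction": UP_IN_C1, "kinase_filter": True, "p_type": p_type},
    )


def consensus(candidate_sets: Sequence[CandidateSet], min_datasets: int = 2) -> ConsensusTable:
    """Count, per gene, the datasets in which it was a candidate.

    A gene untestable (or simply not selected) in a dataset does not vote
    there.  Rows are sorted by descending dataset count, then symbol; the
    unfiltered union is kept alongside the thresholded table.
    """
    if not candidate_sets:
        raise ValueError("need at least one candidate set")
    if min_datasets < 1:
        raise ValueError("min_datasets must be >= 1")
    names = [cs.dataset_name for cs in candidate_sets]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate dataset names: {names}")
    counts: Counter[str] = Counter()
    where: dict[str, list[str]] = {}
    for cs in candidate_sets:
        for gene in cs.genes:
            counts[gene] += 1
            where.setdefault(gene, []).append(cs.dataset_name)
    union = tuple(
        (gene, counts[gene], tuple(where[gene]))
        for gene in sorted(counts, key=lambda g: (-counts[g], g))
    )
    rows = tuple(r for r in union if r[1] >= min_datasets)
    return ConsensusTable(rows=rows, union=union, min_datasets=min_datasets)
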