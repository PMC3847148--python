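"""Readers and writers for every on-disk artifact of the screen.

All formats are plain tab-delimited text:

* expression matrix — genes in rows, samples in columns, first header cell
  is the gene-id column label (a GCT-like variant whose first line begins
  ``#1.2`` is also accepted);
* mutation table — columns ``sample_id``, ``gene``, ``mutation_class``;
* gene list — one symbol per line, ``#`` starts a comment;
* drug-sensitivity matrix — compounds in rows, cell lines in columns,
  entries are normalized −log(GI50) z-scores (higher = more sensitive);
* compound→target map — columns ``compound``, ``targets`` (comma-separated
  gene symbols).

Missing-value dialect for numeric matrices: an empty cell, ``NA`` or
``NaN`` parses as missing; any other non-numeric token is a
:class:`ParseError` naming the offending row and column.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tokens that parse as a missing value in numeric matrices
MISSING_TOKENS = frozenset({"", "NA", "NaN", "nan", "NAN"})

#: controlled vocabulary for TP53 mutation consequence classes
MUTATION_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift", "silent", "synonymous", "noncoding", "none"}
)


class ParseError(ValueError):
    """A file violated the format contract; the message names where."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionDataset:
    """A named log-scale expression matrix (genes × samples).

    ``values[i, j]`` is the log expression of ``genes[i]`` in
    ``samples[j]``; missing entries are NaN.
    """

    name: str
    genes: tuple[str, ...]
    samples: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"dataset {self.name!r}: duplicate gene identifiers")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError(f"dataset {self.name!r}: duplicate sample identifiers")
        if len(self.samples) < 2:
            raise ValueError(f"dataset {self.name!r}: needs at least 2 samples")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"dataset {self.name!r}: matrix shape {self.values.shape} does not "
                f"match {len(self.genes)} genes x {len(self.samples)} samples"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class MutationRecord:
    """One annotated somatic mutation call for one sample."""

    sample_id: str
    gene: str
    mutation_class: str

    def __post_init__(self) -> None:
        if self.mutation_class not in MUTATION_CLASSES:
            raise ValueError(
                f"unknown mutation_class {self.mutation_class!r}; "
                f"allowed: {sorted(MUTATION_CLASSES)}"
            )

    @property
    def is_tp53(self) -> bool:
        return self.gene == "TP53"


@dataclass(frozen=True)
class DrugSensitivityMatrix:
    """Compound × cell-line matrix of normalized −log(GI50) z-scores.

    Orientation: a *higher* z-score means a *lower* GI50, i.e. higher
    sensitivity of that cell line to that compound.
    """

    compounds: tuple[str, ...]
    cell_lines: tuple[str, ...]
    zscores: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.compounds)) != len(self.compounds):
            raise ValueError("duplicate compound names")
        if len(set(self.cell_lines)) != len(self.cell_lines):
            raise ValueError("duplicate cell-line identifiers")
        if self.zscores.shape != (len(self.compounds), len(self.cell_lines)):
            raise ValueError("z-score matrix shape does not match labels")


@dataclass(frozen=True)
class CompoundTargetMap:
    """Mapping from compound name to the gene symbols it targets.

    Compound names are matched case-insensitively after whitespace
    stripping; no synonym resolution is attempted.
    """

    targets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for compound, genes in self.targets.items():
            if not genes:
                raise ValueError(f"compound {compound!r} mapped to an empty target set")

    @staticmethod
    def _key(compound: str) -> str:
        return compound.strip().casefold()

    def lookup(self, compound: str) -> frozenset[str]:
        """Target genes for *compound* (empty set if unmapped)."""
        normalized = {self._key(c): g for c, g in self.targets.items()}
        return normalized.get(self._key(compound), frozenset())


# ---------------------------------------------------------------------------
# matrix reading
# ---------------------------------------------------------------------------


def _read_rows(path: str | Path) -> list[list[str]]:
    with open(path, newline="") as handle:
        return [row for row in csv.reader(handle, delimiter="\t")]


def _parse_cell(token: str, row_id: str, column: str) -> float:
    token = token.strip()
    if token in MISSING_TOKENS:
        return math.nan
    try:
        return float(token)
    except ValueError:
        raise ParseError(
            f"non-numeric cell {token!r} at row {row_id!r}, column {column!r}"
        ) from None


def _parse_matrix(
    rows: list[list[str]],
    what: str,
    duplicate_mode: str = "reject",
) -> tuple[list[str], list[str], np.ndarray]:
    if not rows or len(rows[0]) < 2:
        raise ParseError(f"{what}: malformed header (need an id column and >= 1 data column)")
    header = [cell.strip() for cell in rows[0]]
    columns = header[1:]
    if len(set(columns)) != len(columns):
        seen: set[str] = set()
        dup = next(c for c in columns if c in seen or seen.add(c))  # type: ignore[func-returns-value]
        raise ParseError(f"{what}: repeated column identifier {dup!r}")
    if any(not c for c in columns):
        raise ParseError(f"{what}: empty column identifier in header")

    base_ids: list[str] = []
    counts: dict[str, int] = {}
    data: list[list[float]] = []
    for line_no, row in enumerate(rows[1:], start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        row_id = row[0].strip()
        if not row_id:
            raise ParseError(f"{what}: empty row identifier on line {line_no}")
        if len(row) != len(header):
            raise ParseError(
                f"{what}: row {row_id!r} has {len(row) - 1} cells, expected {len(columns)}"
            )
        if row_id in counts and duplicate_mode == "reject":
            raise ParseError(f"{what}: duplicate row identifier {row_id!r}")
        counts[row_id] = counts.get(row_id, 0) + 1
        base_ids.append(row_id)
        data.append([_parse_cell(c, row_id, col) for c, col in zip(row[1:], columns)])

    if duplicate_mode == "suffix":
        # every occurrence of a duplicated id gets a #k suffix, including the first
        seen: dict[str, int] = {}
        row_ids = []
        for base in base_ids:
            if counts[base] > 1:
                seen[base] = seen.get(base, 0) + 1
                row_ids.append(f"{base}#{seen[base]}")
            else:
                row_ids.append(base)
    else:
        row_ids = base_ids
    values = np.array(data, dtype=float) if data else np.empty((0, len(columns)))
    return row_ids, columns, values


def read_expression(
    path: str | Path, name: str | None = None, probe_mode: str = "reject"
) -> ExpressionDataset:
    """Read a tab-delimited (or GCT-like) log-expression matrix.

    Parameters
    ----------
    path
        TSV with gene ids in the first column and sample ids in the header.
        If the first line begins ``#1.2`` the file is treated as GCT-like:
        the two header lines are skipped and a ``Description`` column, if
        present, is dropped.
    name
        Dataset name; defaults to the file stem.
    probe_mode
        ``"reject"`` (default) errors on duplicate gene rows; ``"suffix"``
        keeps them as ``GENE#1``, ``GENE#2``, … so that multi-probe array
        platforms can be screened probe-wise.
    """
    if probe_mode not in ("reject", "suffix"):
        raise ValueError(f"probe_mode must be 'reject' or 'suffix', got {probe_mode!r}")
    rows = _read_rows(path)
    if rows and rows[0] and rows[0][0].startswith("#1.2"):
        rows = rows[2:]
        if rows and len(rows[0]) >= 2 and rows[0][1].strip().lower() == "description":
            rows = [[row[0]] + row[2:] for row in rows]
    genes, samples, values = _parse_matrix(
        rows, what=str(path), duplicate_mode=probe_mode
    )
    return ExpressionDataset(
        name=name or Path(path).stem,
        genes=tuple(genes),
        samples=tuple(samples),
        values=values,
    )


def read_drug_matrix(path: str | Path) -> DrugSensitivityMatrix:
    """Read a compound × cell-line matrix of −log(GI50) z-scores."""
    compounds, lines, values = _parse_matrix(_read_rows(path), what=str(path))
    return DrugSensitivityMatrix(
        compounds=tuple(compounds), cell_lines=tuple(lines), zscores=values
    )


# ---------------------------------------------------------------------------
# tables and lists
# ---------------------------------------------------------------------------


def read_mutations(path: str | Path) -> list[MutationRecord]:
    """Read a MAF-like TSV of per-sample mutation calls.

    Required columns: ``sample_id``, ``gene``, ``mutation_class``.  Rows
    whose gene is not TP53 are kept (downstream classification ignores
    them) but logged, since this screen only consumes TP53 status.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "gene", "mutation_class"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    records: list[MutationRecord] = []
    for idx, row in frame.iterrows():
        cls = row["mutation_class"].strip()
        if cls not in MUTATION_CLASSES:
            raise ParseError(
                f"{path}: line {int(idx) + 2}: unknown mutation_class {cls!r}; "
                f"allowed: {sorted(MUTATION_CLASSES)}"
            )
        record = MutationRecord(
            sample_id=row["sample_id"].strip(), gene=row["gene"].strip(), mutation_class=cls
        )
        if not record.is_tp53:
            logger.warning(
                "mutation record for sample %s is for gene %s, not TP53",
                record.sample_id,
                record.gene,
            )
        records.append(record)
    return records


def read_gene_list(path: str | Path) -> set[str]:
    """Read a newline-delimited gene list ('#' lines are comments).

    Symbols are whitespace-stripped and deduplicated; case is preserved
    (matching elsewhere is exact and case-sensitive).  An empty list is an
    error: a kinase filter with no kinases is a configuration mistake.
    """
    symbols: set[str] = set()
    with open(path) as handle:
        for line in handle:
            stripped = line.strip()
            if stripped and not stripped.startswith("#"):
                symbols.add(stripped)
    if not symbols:
        raise ParseError(f"{path}: gene list is empty")
    return symbols


def read_target_map(path: str | Path) -> CompoundTargetMap:
    """Read a compound→target TSV (columns ``compound``, ``targets``).

    ``targets`` is a comma-separated list of gene symbols and must be
    non-empty for every mapped compound.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("compound", "targets") if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    mapping: dict[str, frozenset[str]] = {}
    for idx, row in frame.iterrows():
        compound = row["compound"].strip()
        genes = frozenset(g.strip() for g in row["targets"].split(",") if g.strip())
        if not genes:
            raise ParseError(f"{path}: line {int(idx) + 2}: compound {compound!r} has no targets")
        if compound in mapping:
            raise ParseError(f"{path}: duplicate compound {compound!r}")
        mapping[compound] = genes
    return CompoundTargetMap(targets=mapping)


def write_results_table(results: pd.DataFrame, path: str | Path) -> None:
    """Write a pipeline result table as TSV with a deterministic layout.

    The caller is responsible for row order (each table builder sorts by
    its documented key); column order is preserved as given.  Floats are
    written with ``repr`` precision so a write→read→write cycle is
    byte-identical.
    """
    results.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Re-read a table written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


# ---------------------------------------------------------------------------
# writing matrices (used by the synthetic-data generator)
# ---------------------------------------------------------------------------


def _format_cell(x: float) -> str:
    return "NA" if math.isnan(x) else repr(float(x))


def write_expression(dataset: ExpressionDataset, path: str | Path, id_label: str = "gene") -> None:
    """Write an expression matrix in the dialect :func:`read_expression` reads."""
    _write_matrix(dataset.genes, dataset.samples, dataset.values, path, id_label)


def write_drug_matrix(matrix: DrugSensitivityMatrix, path: str | Path) -> None:
    _write_matrix(matrix.compounds, matrix.cell_lines, matrix.zscores, path, "compound")


def _write_matrix(
    row_ids: Sequence[str],
    columns: Sequence[str],
    values: np.ndarray,
    path: str | Path,
    id_label: str,
) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow([id_label, *columns])
        for row_id, row in zip(row_ids, values):
            writer.writerow([row_id, *(_format_cell(x) for x in row)])


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as handle:
        for gene in sorted(set(genes)):
            handle.write(gene + "\n")
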