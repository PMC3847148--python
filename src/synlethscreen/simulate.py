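"""Synthetic input bundles with the statistical structure the screen assumes.

The generator emulates the *shape* of the real inputs — a panel of
log-expression matrices over one set of cell lines, a TP53 mutation table
splitting the lines into a functional-mutant majority and the rest, a
kinase annotation covering a minority of genes, and a compound × line
−log(GI50) z-score matrix — without attempting to match any real
platform's marginal distributions.

Model: per gene, expression is ``baseline + class_effect + N(0, sigma)``
with independent Gaussian noise and a per-gene baseline drawn uniformly
from ``baseline_range`` (cosmetic heterogeneity).  Exactly ``n_planted``
kinase genes carry a ``+effect_size·sigma`` mean shift in the
functional-mutant class, the same genes in every generated dataset.
Target compounds' z-scores are shifted ``+drug_effect`` in mutant lines.
Everything is a deterministic function of ``seed``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .io import (
    CompoundTargetMap,
    DrugSensitivityMatrix,
    ExpressionDataset,
    MutationRecord,
    write_drug_matrix,
    write_expression,
    write_gene_list,
)

FUNCTIONAL_MIX = (("missense", 0.8), ("nonsense", 0.1), ("frameshift", 0.1))
SILENT_MIX = (("silent", 0.4), ("synonymous", 0.4), ("noncoding", 0.2))


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults mirror the NCI-60-like study shape
    (60 lines, 41 functional-p53-mutant) with a 10%-kinase gene universe.
    """

    n_genes: int = 1000
    n_kinases: int = 100
    n_samples: int = 60
    n_mutant: int = 41
    n_planted: int = 10
    effect_size: float = 1.5  # mean shift in units of sigma
    sigma: float = 1.0  # residual SD of log expression
    missing_rate: float = 0.0
    n_datasets: int = 3
    n_compounds: int = 30
    n_target_compounds: int = 10
    drug_effect: float = 1.0  # z-score shift for target compounds in c1
    silent_fraction: float = 0.3  # fraction of c2 samples given a silent record
    baseline_range: tuple[float, float] = (4.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_planted <= self.n_kinases <= self.n_genes):
            raise ValueError("need n_planted <= n_kinases <= n_genes")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not (0 < self.n_mutant < self.n_samples):
            raise ValueError("need 0 < n_mutant < n_samples")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        if not (0 <= self.n_target_compounds <= self.n_compounds):
            raise ValueError("need n_target_compounds <= n_compounds")
        if not (0.0 <= self.silent_fraction <= 1.0):
            raise ValueError("silent_fraction must be in [0, 1]")
        if not self.baseline_range[0] < self.baseline_range[1]:
            raise ValueError("baseline_range must be increasing")


@dataclass(frozen=True)
class Truth:
    """Ground truth of one simulated bundle."""

    planted_genes: tuple[str, ...]
    target_compounds: tuple[str, ...]
    mutant_samples: tuple[str, ...]
    silent_samples: tuple[str, ...]


@dataclass(frozen=True)
class Bundle:
    """Everything one end-to-end run of the screen consumes."""

    config: SimulationConfig
    datasets: tuple[ExpressionDataset, ...]
    mutations: tuple[MutationRecord, ...]
    kinases: frozenset[str]
    drug_matrix: DrugSensitivityMatrix
    target_map: CompoundTargetMap
    truth: Truth


def _draw_classes(rng: np.random.Generator, mix) -> str:
    names = [m[0] for m in mix]
    probs = np.array([m[1] for m in mix])
    return str(rng.choice(names, p=probs / probs.sum()))


def simulate_bundle(config: SimulationConfig) -> Bundle:
    """Generate a full input bundle from *config* (deterministic in seed)."""
    rng = np.random.default_rng(config.seed)

    width = max(4, len(str(config.n_genes)))
    kinase_genes = [f"KIN{i + 1:0{width}d}" for i in range(config.n_kinases)]
    other_genes = [f"GEN{i + 1:0{width}d}" for i in range(config.n_genes - config.n_kinases)]
    genes = kinase_genes + other_genes
    planted = sorted(rng.choice(kinase_genes, size=config.n_planted, replace=False).tolist())
    planted_idx = np.array([genes.index(g) for g in planted], dtype=int)

    samples = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    mutant = sorted(rng.choice(samples, size=config.n_mutant, replace=False).tolist())
    mutant_mask = np.isin(np.array(samples), mutant)

    # mutation table: one functional record per mutant line, silent records
    # for a fraction of the rest (exercising the non-functional grouping)
    records: list[MutationRecord] = []
    for s in mutant:
        records.append(MutationRecord(s, "TP53", _draw_classes(rng, FUNCTIONAL_MIX)))
    non_mutant = [s for s in samples if s not in set(mutant)]
    n_silent = int(round(config.silent_fraction * len(non_mutant)))
    silent = sorted(rng.choice(non_mutant, size=n_silent, replace=False).tolist()) if n_silent else []
    for s in silent:
        records.append(MutationRecord(s, "TP53", _draw_classes(rng, SILENT_MIX)))

    # expression panels: shared planted genes and class structure,
    # independently drawn baselines and noise per dataset
    lo, hi = config.baseline_range
    datasets = []
    for d in range(config.n_datasets):
        baseline = rng.uniform(lo, hi, size=config.n_genes)
        values = baseline[:, None] + rng.normal(0.0, config.sigma, (config.n_genes, config.n_samples))
        shift = np.zeros((config.n_genes, config.n_samples))
        shift[np.ix_(planted_idx, np.flatnonzero(mutant_mask))] = config.effect_size * config.sigma
        values = values + shift
        if config.missing_rate > 0:
            values[rng.random(values.shape) < config.missing_rate] = np.nan
        datasets.append(
            ExpressionDataset(
                name=f"sim{d + 1}",
                genes=tuple(genes),
                samples=tuple(samples),
                values=values,
            )
        )

    # drug matrix: target compounds hit planted genes and are up-shifted in
    # the mutant lines; the rest target non-planted kinases, no shift
    compounds = [f"drug{i + 1:03d}" for i in range(config.n_compounds)]
    target_compounds = sorted(
        rng.choice(compounds, size=config.n_target_compounds, replace=False).tolist()
    )
    non_planted_kinases = [g for g in kinase_genes if g not in set(planted)]
    mapping: dict[str, frozenset[str]] = {}
    for compound in compounds:
        if compound in set(target_compounds) and planted:
            k = int(rng.integers(1, min(3, config.n_planted) + 1))
            mapping[compound] = frozenset(rng.choice(planted, size=k, replace=False).tolist())
        elif non_planted_kinases:
            k = int(rng.integers(1, min(2, len(non_planted_kinases)) + 1))
            mapping[compound] = frozenset(
                rng.choice(non_planted_kinases, size=k, replace=False).tolist()
            )
    zscores = rng.normal(0.0, 1.0, (config.n_compounds, config.n_samples))
    target_rows = np.array([c in set(target_compounds) for c in compounds])
    zscores[np.ix_(target_rows, mutant_mask)] += config.drug_effect

    return Bundle(
        config=config,
        datasets=tuple(datasets),
        mutations=tuple(records),
        kinases=frozenset(kinase_genes),
        drug_matrix=DrugSensitivityMatrix(
            compounds=tuple(compounds), cell_lines=tuple(samples), zscores=zscores
        ),
        target_map=CompoundTargetMap(targets=mapping),
        truth=Truth(
            planted_genes=tuple(planted),
            target_compounds=tuple(target_compounds),
            mutant_samples=tuple(mutant),
            silent_samples=tuple(silent),
        ),
    )


def write_bundle(bundle: Bundle, directory: str | Path) -> None:
    """Write every bundle artifact in the dialects the readers accept.

    Produces one ``expression_<name>.tsv`` per dataset, ``mutations.tsv``,
    ``kinases.txt``, ``gi50.tsv``, ``targets.tsv``, ``truth.tsv`` and a
    ``manifest.yaml`` recording the config (and therefore the seed).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ds in bundle.datasets:
        write_expression(ds, directory / f"expression_{ds.name}.tsv")
    with open(directory / "mutations.tsv", "w") as handle:
        handle.write("sample_id\tgene\tmutation_class\n")
        for r in bundle.mutations:
            handle.write(f"{r.sample_id}\t{r.gene}\t{r.mutation_class}\n")
    write_gene_list(bundle.kinases, directory / "kinases.txt")
    write_drug_matrix(bundle.drug_matrix, directory / "gi50.tsv")
    with open(directory / "targets.tsv", "w") as handle:
        handle.write("compound\ttargets\n")
        for compound in bundle.drug_matrix.compounds:
            targets = bundle.target_map.targets.get(compound)
            if targets:
                handle.write(f"{compound}\t{','.join(sorted(targets))}\n")
    with open(directory / "truth.tsv", "w") as handle:
        handle.write("kind\tname\n")
        for gene in bundle.truth.planted_genes:
            handle.write(f"planted_gene\t{gene}\n")
        for compound in bundle.truth.target_compounds:
            handle.write(f"target_compound\t{compound}\n")
        for sample in bundle.truth.mutant_samples:
            handle.write(f"mutant_sample\t{sample}\n")
        for sample in bundle.truth.silent_samples:
            handle.write(f"silent_sample\t{sample}\n")
    config = asdict(bundle.config)
    config["baseline_range"] = list(config["baseline_range"])
    with open(directory / "manifest.yaml", "w") as handle:
        yaml.safe_dump({"config": config}, handle, sort_keys=True)


def load_config(path: str | Path) -> SimulationConfig:
    """Read a YAML config mirroring :class:`SimulationConfig` field-for-field."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    if "config" in raw and isinstance(raw["config"], dict):
        raw = raw["config"]
    if "baseline_range" in raw:
        raw["baseline_range"] = tuple(raw["baseline_range"])
    return SimulationConfig(**raw)
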