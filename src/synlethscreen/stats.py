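"""Per-gene two-class statistics: t/F tests, label-permutation p-values,
and Benjamini–Hochberg FDR.

The screen tests every gene for differential log expression between the
functional-p53-mutant class (c1) and the rest (c2) with a univariate
two-sample t test (pooled variance by default, Welch by flag), measures
significance non-parametrically by permuting the class labels — the
permutation p-value is the proportion of label permutations whose
parametric p is at least as small as the observed one — and estimates the
false discovery rate over all testable genes with the Benjamini–Hochberg
step-up procedure.

Implementation notes.  The t statistic is computed from per-class sums and
sums of squares so that thousands of label permutations can be evaluated
for a whole gene block with two matrix products; values are centered per
gene first to keep the sums-of-squares subtraction well conditioned.
Genes are grouped by their missing-value pattern, so all genes sharing a
pattern share one set of permutations (and one exhaustive enumeration when
the assignment space is small).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionDataset
from .p53 import ClassLabels

logger = logging.getLogger(__name__)

#: absolute guard when comparing permutation p-values against the observed
#: one ("as small as" with ties counted, robust to last-ulp float noise)
_P_TIE_TOL = 1e-12

#: soft cap on elements per permutation block (memory control)
_BLOCK_ELEMENTS = 20_000_000

UP_IN_C1 = "up_in_c1"
UP_IN_C2 = "up_in_c2"
TIE = "tie"


class UntestableGeneError(ValueError):
    """Fewer than 2 non-missing values in a class; no test is possible."""


@dataclass(frozen=True)
class PermutationScheme:
    """How label permutations are generated.

    ``mode="monte_carlo"`` draws ``n_permutations`` random c1-subsets
    (with replacement from the assignment space); ``"exhaustive"``
    enumerates every distinct c1/c2 assignment exactly once; ``"auto"``
    (default) uses the exhaustive enumeration whenever the number of
    distinct assignments is at most ``n_permutations``.
    """

    n_permutations: int = 10_000
    seed: int = 0
    mode: str = "auto"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.mode not in ("monte_carlo", "exhaustive", "auto"):
            raise ValueError(f"unknown permutation mode {self.mode!r}")

    def resolve_mode(self, n: int, n1: int) -> str:
        if self.mode != "auto":
            return self.mode
        return "exhaustive" if math.comb(n, n1) <= self.n_permutations else "monte_carlo"


@dataclass(frozen=True)
class GeneTestResult:
    """Outcome of the two-class comparison for one gene (complete-case)."""

    gene: str
    n1: int
    n2: int
    mean1: float
    mean2: float
    statistic: float
    parametric_p: float
    permutation_p: float  # NaN when permutation testing was not run
    q_value: float
    direction: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.parametric_p <= 1.0):
            raise ValueError(f"{self.gene}: parametric_p outside [0, 1]")
        if not (0.0 <= self.q_value <= 1.0):
            raise ValueError(f"{self.gene}: q_value outside [0, 1]")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError(f"{self.gene}: class counts below 2")


@dataclass(frozen=True)
class ClassComparisonResult:
    """All per-gene results of one dataset run, plus the settings used."""

    dataset_name: str
    results: tuple[GeneTestResult, ...]
    alpha: float
    variance_mode: str
    untestable_genes: tuple[str, ...]

    def __iter__(self) -> Iterator[GeneTestResult]:
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    def to_frame(self) -> pd.DataFrame:
        """Table sorted by permutation p (parametric p where absent), then gene."""
        frame = pd.DataFrame(
            {
                "gene": [r.gene for r in self.results],
                "n1": [r.n1 for r in self.results],
                "n2": [r.n2 for r in self.results],
                "mean1": [r.mean1 for r in self.results],
                "mean2": [r.mean2 for r in self.results],
                "statistic": [r.statistic for r in self.results],
                "parametric_p": [r.parametric_p for r in self.results],
                "permutation_p": [r.permutation_p for r in self.results],
                "q_value": [r.q_value for r in self.results],
                "direction": [r.direction for r in self.results],
            }
        )
        sort_p = frame["permutation_p"].fillna(frame["parametric_p"])
        order = np.lexsort((frame["gene"].to_numpy(), sort_p.to_numpy()))
        return frame.iloc[order].reset_index(drop=True)


# ---------------------------------------------------------------------------
# t / F statistics from per-class moments
# ---------------------------------------------------------------------------


def _t_p_from_sums(sum1, ss1, n1: int, sum2, ss2, n2: int, variance_mode: str):
    """t statistic and two-sided p from per-class sums and sums of squares.

    Degenerate cases: zero standard error with equal means gives t = 0,
    p = 1; zero standard error with unequal means gives t = ±inf, p = 0.
    """
    sum1 = np.asarray(sum1, dtype=float)
    ss1 = np.asarray(ss1, dtype=float)
    sum2 = np.asarray(sum2, dtype=float)
    ss2 = np.asarray(ss2, dtype=float)
    mean1 = sum1 / n1
    mean2 = sum2 / n2
    # clip: ss - sum^2/n can go slightly negative from rounding
    var1 = np.maximum(ss1 - sum1 * mean1, 0.0) / (n1 - 1)
    var2 = np.maximum(ss2 - sum2 * mean2, 0.0) / (n2 - 1)
    diff = mean1 - mean2
    if variance_mode == "pooled":
        sp2 = ((n1 - 1) * var1 + (n2 - 1) * var2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = np.broadcast_to(float(n1 + n2 - 2), se2.shape).copy()
    elif variance_mode == "welch":
        a = var1 / n1
        b = var2 / n2
        se2 = a + b
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2 * se2 / (a * a / (n1 - 1) + b * b / (n2 - 1))
    else:
        raise ValueError(f"variance_mode must be 'pooled' or 'welch', got {variance_mode!r}")
    zero_se = se2 <= 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    t = np.where(zero_se, np.sign(diff) * np.where(diff == 0.0, 0.0, np.inf), t)
    df = np.where(zero_se, 1.0, df)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return t, np.minimum(p, 1.0)


def _clean_pair(x1, x2) -> tuple[np.ndarray, np.ndarray]:
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    x1 = x1[~np.isnan(x1)]
    x2 = x2[~np.isnan(x2)]
    if x1.size < 2 or x2.size < 2:
        raise UntestableGeneError(
            f"need >= 2 non-missing values per class, got {x1.size} and {x2.size}"
        )
    return x1, x2


def t_test_two_sided(
    x1: Sequence[float], x2: Sequence[float], variance_mode: str = "pooled"
) -> tuple[float, float]:
    """Two-sample t test; returns ``(statistic, two_sided_p)``.

    The statistic carries the sign of ``mean(x1) - mean(x2)``.  Missing
    values are dropped per vector; fewer than two values in either class
    raises :class:`UntestableGeneError`.
    """
    x1, x2 = _clean_pair(x1, x2)
    center = np.concatenate([x1, x2]).mean()
    v1 = x1 - center
    v2 = x2 - center
    t, p = _t_p_from_sums(
        v1.sum(), (v1 * v1).sum(), x1.size, v2.sum(), (v2 * v2).sum(), x2.size, variance_mode
    )
    return float(t), float(p)


def f_test(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """One-way ANOVA F and its upper-tail p across ``len(groups)`` classes.

    With exactly two groups, F equals the square of the pooled-variance t
    statistic and the p-values coincide.  Degenerate inputs: all
    within-group variance zero gives p = 0 when group means differ and
    p = 1 when they are all equal.
    """
    cleaned = []
    for g in groups:
        arr = np.asarray(g, dtype=float).ravel()
        arr = arr[~np.isnan(arr)]
        if arr.size < 2:
            raise UntestableGeneError("each group needs >= 2 non-missing values")
        cleaned.append(arr)
    if len(cleaned) < 2:
        raise ValueError("need at least 2 groups")
    k = len(cleaned)
    total = np.concatenate(cleaned)
    n_total = total.size
    if n_total - k < 1:
        raise ValueError("within-group degrees of freedom must be positive")
    grand = total.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in cleaned)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in cleaned)
    df_between = k - 1
    df_within = n_total - k
    if ss_within <= 0.0:
        return (0.0, 1.0) if ss_between <= 0.0 else (math.inf, 0.0)
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    return float(f_stat), float(sps.f.sf(f_stat, df_between, df_within))


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------


def _exhaustive_mask_blocks(n: int, n1: int, block: int) -> Iterator[np.ndarray]:
    """Boolean c1-membership matrices covering every distinct assignment once."""
    combos = itertools.combinations(range(n), n1)
    while True:
        batch = list(itertools.islice(combos, block))
        if not batch:
            return
        masks = np.zeros((len(batch), n), dtype=bool)
        rows = np.repeat(np.arange(len(batch)), n1)
        masks[rows, np.concatenate([np.fromiter(c, int, n1) for c in batch])] = True
        yield masks


def _random_mask_block(rng: np.random.Generator, n: int, n1: int, block: int) -> np.ndarray:
    """Uniformly random c1-subsets of size n1 (one per row)."""
    u = rng.random((block, n))
    idx = np.argpartition(u, n1 - 1, axis=1)[:, :n1]
    masks = np.zeros((block, n), dtype=bool)
    np.put_along_axis(masks, idx, True, axis=1)
    return masks


def _perm_exceed_counts(
    block_values: np.ndarray,
    masks: np.ndarray,
    n1: int,
    p_obs: np.ndarray,
    variance_mode: str,
) -> np.ndarray:
    """#permutations (columns of the block) with p <= observed, per gene.

    ``block_values`` is (genes, n) row-centered; ``masks`` is (perms, n).
    """
    n = block_values.shape[1]
    n2 = n - n1
    m = masks.astype(float)
    sum1 = block_values @ m.T
    ss1 = (block_values * block_values) @ m.T
    tot = block_values.sum(axis=1, keepdims=True)
    tot2 = (block_values * block_values).sum(axis=1, keepdims=True)
    _, p_perm = _t_p_from_sums(sum1, ss1, n1, tot - sum1, tot2 - ss1, n2, variance_mode)
    return (p_perm <= p_obs[:, None] + _P_TIE_TOL).sum(axis=1)


def _permutation_p_block(
    values: np.ndarray,
    mask_c1: np.ndarray,
    p_obs: np.ndarray,
    scheme: PermutationScheme,
    rng: np.random.Generator,
    variance_mode: str,
) -> np.ndarray:
    """Permutation p for a (genes, n) block sharing one complete-case layout."""
    n = values.shape[1]
    n1 = int(mask_c1.sum())
    mode = scheme.resolve_mode(n, n1)
    n_genes = values.shape[0]
    block = max(64, _BLOCK_ELEMENTS // max(n_genes, 1))
    counts = np.zeros(n_genes, dtype=np.int64)
    if mode == "exhaustive":
        total = math.comb(n, n1)
        for masks in _exhaustive_mask_blocks(n, n1, block):
            counts += _perm_exceed_counts(values, masks, n1, p_obs, variance_mode)
        return counts / total
    done = 0
    while done < scheme.n_permutations:
        b = min(block, scheme.n_permutations - done)
        masks = _random_mask_block(rng, n, n1, b)
        counts += _perm_exceed_counts(values, masks, n1, p_obs, variance_mode)
        done += b
    return (1.0 + counts) / (1.0 + scheme.n_permutations)


def permutation_p(
    values: Sequence[float],
    mask_c1: Sequence[bool],
    scheme: PermutationScheme,
    variance_mode: str = "pooled",
) -> float:
    """Label-permutation p-value for a single gene.

    The p-value is the proportion of class-label permutations whose
    parametric (t-test) p-value is at least as small as the one obtained
    with the true labels.  In Monte-Carlo mode the estimate is smoothed as
    ``(1 + #{p_perm <= p_obs}) / (1 + n_permutations)`` so it can never be
    zero; in exhaustive mode the observed assignment is one of the
    enumerated ones, so the proportion is positive by construction.
    Deterministic given ``scheme.seed``.
    """
    values = np.asarray(values, dtype=float).ravel()
    mask_c1 = np.asarray(mask_c1, dtype=bool).ravel()
    if values.shape != mask_c1.shape:
        raise ValueError("values and labels have different lengths")
    present = ~np.isnan(values)
    values = values[present]
    mask_c1 = mask_c1[present]
    x1 = values[mask_c1]
    x2 = values[~mask_c1]
    if x1.size < 2 or x2.size < 2:
        raise UntestableGeneError(
            f"need >= 2 non-missing values per class, got {x1.size} and {x2.size}"
        )
    _, p_obs = t_test_two_sided(x1, x2, variance_mode)
    centered = (values - values.mean())[None, :]
    rng = np.random.default_rng(scheme.seed)
    out = _permutation_p_block(
        centered, mask_c1, np.array([p_obs]), scheme, rng, variance_mode
    )
    return float(out[0])


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving with the input.

    ``q_i = min_{j: p_(j) >= p_(i)} m * p_(j) / rank(j)``, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# full dataset run
# ---------------------------------------------------------------------------


def run_class_comparison(
    dataset: ExpressionDataset,
    labels: ClassLabels,
    scheme: PermutationScheme | None = PermutationScheme(),
    alpha: float = 0.05,
    variance_mode: str = "pooled",
    universe: frozenset[str] | set[str] | None = None,
) -> ClassComparisonResult:
    """Run the per-gene two-class comparison over a whole dataset.

    Per gene, a complete-case t test (two-sided, *variance_mode*) compares
    c1 against c2; genes with fewer than two values in either class are
    untestable and are excluded from the FDR computation (and logged).
    Permutation p-values use *scheme* (pass ``None`` to skip the
    permutation stage); q-values are Benjamini–Hochberg over the
    parametric p-values of all testable genes.

    ``universe`` optionally restricts the multiple-testing universe (and
    the reported results) to a gene subset — e.g. the kinome — before
    testing; probe-suffixed identifiers (``GENE#2``) match on their base
    symbol.  By default the universe is every gene in the dataset.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    mask = labels.mask(dataset.samples)
    values = np.asarray(dataset.values, dtype=float)

    if universe is not None:
        keep = [
            i
            for i, g in enumerate(dataset.genes)
            if g.split("#", 1)[0] in universe
        ]
        gene_names = [dataset.genes[i] for i in keep]
        values = values[keep]
    else:
        gene_names = list(dataset.genes)

    # group genes by missing-value pattern so permutations are shared
    groups: dict[bytes, list[int]] = {}
    present_matrix = ~np.isnan(values)
    for i in range(len(gene_names)):
        groups.setdefault(present_matrix[i].tobytes(), []).append(i)

    rng = np.random.default_rng(scheme.seed) if scheme is not None else None
    per_gene: dict[int, dict] = {}
    untestable: list[str] = []

    for key in sorted(groups, key=lambda k: groups[k][0]):
        idx = groups[key]
        present = present_matrix[idx[0]]
        sub_mask = mask[present]
        n1 = int(sub_mask.sum())
        n2 = int((~sub_mask).sum())
        if n1 < 2 or n2 < 2:
            untestable.extend(gene_names[i] for i in idx)
            continue
        block = values[np.ix_(idx, np.flatnonzero(present))]
        centered = block - block.mean(axis=1, keepdims=True)
        x1 = block[:, sub_mask]
        x2 = block[:, ~sub_mask]
        c1 = centered[:, sub_mask]
        c2 = centered[:, ~sub_mask]
        t_obs, p_obs = _t_p_from_sums(
            c1.sum(axis=1),
            (c1 * c1).sum(axis=1),
            n1,
            c2.sum(axis=1),
            (c2 * c2).sum(axis=1),
            n2,
            variance_mode,
        )
        if scheme is not None:
            perm = _permutation_p_block(centered, sub_mask, p_obs, scheme, rng, variance_mode)
        else:
            perm = np.full(len(idx), np.nan)
        mean1 = x1.mean(axis=1)
        mean2 = x2.mean(axis=1)
        for j, i in enumerate(idx):
            per_gene[i] = {
                "gene": gene_names[i],
                "n1": n1,
                "n2": n2,
                "mean1": float(mean1[j]),
                "mean2": float(mean2[j]),
                "statistic": float(t_obs[j]),
                "parametric_p": float(p_obs[j]),
                "permutation_p": float(perm[j]),
            }

    if untestable:
        logger.info(
            "%d gene(s) untestable (< 2 values in a class) and excluded from FDR: %s%s",
            len(untestable),
            ", ".join(untestable[:5]),
            "…" if len(untestable) > 5 else "",
        )
    if not per_gene:
        raise ValueError(f"dataset {dataset.name!r}: no testable genes")

    ordered = sorted(per_gene)
    qvals = bh_fdr([per_gene[i]["parametric_p"] for i in ordered])
    results = []
    for q, i in zip(qvals, ordered):
        row = per_gene[i]
        diff = row["mean1"] - row["mean2"]
        direction = UP_IN_C1 if diff > 0 else (UP_IN_C2 if diff < 0 else TIE)
        results.append(GeneTestResult(q_value=float(q), direction=direction, **row))
    return ClassComparisonResult(
        dataset_name=dataset.name,
        results=tuple(results),
        alpha=alpha,
        variance_mode=variance_mode,
        untestable_genes=tuple(untestable),
    )
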