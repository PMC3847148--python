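"""Drug-sensitivity comparison between the two cell-line classes.

Compound sensitivity is given as normalized −log(GI50) z-scores, so a
*higher* z-score means a lower GI50, i.e. higher sensitivity.  For each
compound mapped to a candidate gene, a one-sided t test asks whether the
functional-p53-mutant lines (c1) are *more* sensitive — alternative
``mean_c1 > mean_c2``.  p-values are reported raw (no multiple-testing
adjustment): with few mutant lines the power of this comparison is
limited, and the screen treats it as a directional sanity check rather
than a discovery procedure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CompoundTargetMap, DrugSensitivityMatrix
from .p53 import ClassLabels
from .stats import UntestableGeneError, t_test_two_sided

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DrugComparisonResult:
    """One-sided class comparison for one compound (complete-case)."""

    compound: str
    mean_c1: float
    mean_c2: float
    n1: int
    n2: int
    one_sided_p: float
    targets: frozenset[str]

    def __post_init__(self) -> None:
        if not (0.0 <= self.one_sided_p <= 1.0):
            raise ValueError(f"{self.compound}: one_sided_p outside [0, 1]")

    @property
    def concordant(self) -> bool:
        """Higher mean sensitivity in the functional-mutant lines."""
        return self.mean_c1 > self.mean_c2


def compare_compound(
    compound: str,
    zrow,
    mask_c1,
    targets: frozenset[str] = frozenset(),
    variance_mode: str = "pooled",
) -> DrugComparisonResult:
    """One-sided t test of one compound's z-scores, c1 vs c2.

    ``one_sided_p`` is the upper tail of the t distribution at the
    observed statistic (alternative: higher sensitivity, i.e. higher
    −log(GI50) z-score, in the functional-p53-mutant lines).  When the
    statistic is zero the p-value is exactly 0.5.  Missing z-scores are
    dropped per class; fewer than two values in either class raises
    :class:`~synlethscreen.stats.UntestableGeneError`.
    """
    zrow = np.asarray(zrow, dtype=float).ravel()
    mask_c1 = np.asarray(mask_c1, dtype=bool).ravel()
    if zrow.shape != mask_c1.shape:
        raise ValueError("z-score row and labels have different lengths")
    x1 = zrow[mask_c1]
    x2 = zrow[~mask_c1]
    x1 = x1[~np.isnan(x1)]
    x2 = x2[~np.isnan(x2)]
    if x1.size < 2 or x2.size < 2:
        raise UntestableGeneError(
            f"compound {compound!r}: need >= 2 z-scores per class, "
            f"got {x1.size} and {x2.size}"
        )
    t, two_sided = t_test_two_sided(x1, x2, variance_mode)
    # upper tail: p = p2/2 when t favors the alternative, 1 - p2/2 otherwise
    if t > 0:
        one_sided = two_sided / 2.0
    elif t < 0:
        one_sided = 1.0 - two_sided / 2.0
    else:
        one_sided = 0.5
    return DrugComparisonResult(
        compound=compound,
        mean_c1=float(x1.mean()),
        mean_c2=float(x2.mean()),
        n1=x1.size,
        n2=x2.size,
        one_sided_p=float(one_sided),
        targets=frozenset(targets),
    )


def screen_compounds(
    matrix: DrugSensitivityMatrix,
    target_map: CompoundTargetMap,
    candidates,
    labels: ClassLabels,
    variance_mode: str = "pooled",
    include_all: bool = False,
) -> list[DrugComparisonResult]:
    """Test every compound whose target set intersects the candidates.

    With ``include_all=True`` every compound in the matrix is tested
    regardless of its target annotation (useful for ranking candidates'
    compounds against the rest).  Untestable compounds (fewer than two
    usable z-scores in a class) are skipped with a log message.  Results
    are sorted by ascending one-sided p, ties broken by compound name.
    """
    candidate_set = set(candidates)
    mask = labels.mask(matrix.cell_lines)
    results: list[DrugComparisonResult] = []
    n_considered = 0
    for i, compound in enumerate(matrix.compounds):
        targets = target_map.lookup(compound)
        if not include_all and not (targets & candidate_set):
            continue
        n_considered += 1
        try:
            results.append(
                compare_compound(compound, matrix.zscores[i], mask, targets, variance_mode)
            )
        except UntestableGeneError as exc:
            logger.info("skipping untestable compound: %s", exc)
    if n_considered == 0:
        logger.warning(
            "no compound targets any of the %d candidate genes; empty result",
            len(candidate_set),
        )
    results.sort(key=lambda r: (r.one_sided_p, r.compound))
    return results


def drug_results_to_frame(results) -> pd.DataFrame:
    """Table mirroring the per-compound report: means, p, targets."""
    return pd.DataFrame(
        {
            "compound": [r.compound for r in results],
            "mean_c1": [r.mean_c1 for r in results],
            "mean_c2": [r.mean_c2 for r in results],
            "n1": [r.n1 for r in results],
            "n2": [r.n2 for r in results],
            "one_sided_p": [r.one_sided_p for r in results],
            "concordant": [r.concordant for r in results],
            "targets": [",".join(sorted(r.targets)) for r in results],
        }
    )
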