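"""Two-group differential expression for raw counts, and cancer-specific DEG sets.

The test is a deliberately small re-implementation of the common
negative-binomial workflow: median-of-ratios size factors, gene-wise
method-of-moments dispersion pooled across the two groups, and a Wald test
on the log-scale group-mean contrast (t reference with nA+nB-2 degrees of
freedom as a small-sample adjustment).  There is no dispersion shrinkage and
no fold-change shrinkage; with the strict thresholds used downstream
(adjusted P < 0.001, |log2FC| > 1) set-level behaviour on well-separated
effects is what matters.  An externally computed DEG table can be dropped in
anywhere a :class:`DegTable` is accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .expression_io import ExpressionMatrix

logger = logging.getLogger(__name__)

DEG_ALPHA = 1e-3
DEG_MIN_ABS_LFC = 1.0
_DISPERSION_FLOOR = 1e-8
_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of gene ids."""

    label: str
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass
class DegTable:
    """Per-gene differential-expression statistics (group A over group B)."""

    table: pd.DataFrame  # columns: baseMean, log2FoldChange, pvalue, padj, direction
    excluded_genes: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.table)


def size_factors(matrix: ExpressionMatrix | pd.DataFrame, allow_pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    The reference is the per-gene geometric mean over samples, restricted to
    genes expressed (count > 0) in every sample; each sample's factor is the
    median ratio of its counts to the reference.  Factors are returned as
    computed, without rescaling.  When no gene is expressed everywhere, a
    pseudocount reference can be enabled with ``allow_pseudo_reference``.
    """
    counts = matrix.counts if isinstance(matrix, ExpressionMatrix) else matrix
    vals = counts.to_numpy(dtype=float)
    allpos = (vals > 0).all(axis=1)
    if not allpos.any():
        if not allow_pseudo_reference:
            raise ValueError(
                "no gene has nonzero counts in all samples; "
                "re-run with allow_pseudo_reference=True to use a pseudocount reference"
            )
        work = vals + 0.5
        allpos = np.ones(vals.shape[0], dtype=bool)
    else:
        work = vals
    sub = work[allpos]
    log_geo = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_geo[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def nb_deg_test(
    matrix: ExpressionMatrix,
    group_a: Iterable[str],
    group_b: Iterable[str],
    factors: pd.Series | None = None,
) -> DegTable:
    """Negative-binomial Wald test of group A vs group B on raw counts.

    Genes with all-zero counts in both groups are excluded from the table
    and reported in ``excluded_genes``.
    """
    group_a, group_b = list(group_a), list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    counts = matrix.counts
    missing = (set(group_a) | set(group_b)) - set(counts.columns)
    if missing:
        raise ValueError(f"unknown samples: {sorted(missing)[:5]}")
    if factors is None:
        factors = size_factors(matrix)
    norm = counts.loc[:, group_a + group_b].to_numpy(dtype=float) / factors.loc[
        group_a + group_b
    ].to_numpy()
    nA, nB = len(group_a), len(group_b)
    A, B = norm[:, :nA], norm[:, nA:]

    nonzero = (A.sum(axis=1) + B.sum(axis=1)) > 0
    excluded = [g for g, keep in zip(counts.index, nonzero) if not keep]
    if excluded:
        logger.info("nb_deg_test: excluding %d all-zero genes", len(excluded))
    A, B = A[nonzero], B[nonzero]
    genes = counts.index[nonzero]

    mA, mB = A.mean(axis=1), B.mean(axis=1)
    vA, vB = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
    num = (nA - 1) * (vA - mA) + (nB - 1) * (vB - mB)
    den = (nA - 1) * mA**2 + (nB - 1) * mB**2
    disp = np.maximum(num / np.maximum(den, 1e-300), _DISPERSION_FLOOR)

    var_mA = mA + disp * mA**2
    var_mB = mB + disp * mB**2
    se = np.sqrt(
        var_mA / (nA * (mA + _PSEUDOCOUNT) ** 2) + var_mB / (nB * (mB + _PSEUDOCOUNT) ** 2)
    )
    lfc = np.log2((mA + _PSEUDOCOUNT) / (mB + _PSEUDOCOUNT))
    wald = np.log((mA + _PSEUDOCOUNT) / (mB + _PSEUDOCOUNT)) / se
    pvalue = 2.0 * stats.t.sf(np.abs(wald), df=nA + nB - 2)
    table = pd.DataFrame(
        {
            "baseMean": (A.sum(axis=1) + B.sum(axis=1)) / (nA + nB),
            "log2FoldChange": lfc,
            "pvalue": pvalue,
            "padj": bh_adjust(pvalue),
            "direction": np.where(lfc >= 0, "up", "down"),
        },
        index=genes,
    )
    return DegTable(table, excluded_genes=excluded)


def select_degs(
    deg: DegTable,
    alpha: float = DEG_ALPHA,
    min_abs_lfc: float = DEG_MIN_ABS_LFC,
    label: str = "DEG",
) -> GeneSet:
    """Genes with adjusted p strictly below ``alpha`` and |log2FC| strictly above ``min_abs_lfc``."""
    t = deg.table
    mask = (t["padj"] < alpha) & (t["log2FoldChange"].abs() > min_abs_lfc)
    return GeneSet(label, frozenset(t.index[mask]))


def cancer_specific_degs(tumor_degs: GeneSet, normal_degs: GeneSet) -> tuple[GeneSet, dict[str, int]]:
    """Tumor DEGs minus normal DEGs, with a Venn summary of the set sizes."""
    shared = tumor_degs.genes & normal_degs.genes
    result = GeneSet("cancer_specific", tumor_degs.genes - normal_degs.genes)
    summary = {
        "tumor": len(tumor_degs.genes),
        "normal": len(normal_degs.genes),
        "intersection": len(shared),
        "cancer_specific": len(result.genes),
    }
    return result, summary
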