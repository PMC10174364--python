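"""Cancer-specific bicluster selection by Fisher-exact sample-composition tests.

For every bicluster and every candidate tumor class (tumors of one tissue),
a 2x2 table of bicluster membership against class membership is built over
the whole cohort (normals included) and tested with a two-sided Fisher
exact test.  q-values are Benjamini-Hochberg over the full family of
bicluster x class tests; a bicluster is cancer-specific when at least one
class reaches q < 0.001 with odds ratio > 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb, inf, nan

import pandas as pd

from ._stats import bh_adjust
from .biclustering import Bicluster, BiclusterSet
from .expression_io import SampleTable

logger = logging.getLogger(__name__)

Q_THRESHOLD = 1e-3


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact p and sample odds ratio for a 2x2 table.

    ``table`` is ``[[a, b], [c, d]]`` with nonnegative integer counts.  The
    p-value sums the probabilities of all margin-fixed tables whose
    hypergeometric probability does not exceed that of the observed table;
    the comparison is done in exact integer arithmetic.  The odds ratio is
    the cross-product ratio a*d/(b*c), infinity when only b*c is zero.
    """
    (a, b), (c, d) = table
    cells = [a, b, c, d]
    if any(int(x) != x for x in cells):
        raise ValueError("table entries must be integers")
    a, b, c, d = (int(x) for x in cells)
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be nonnegative")
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        p = 1.0  # degenerate margin: only one table is possible
    else:
        lo, hi = max(0, r1 + c1 - n), min(r1, c1)
        # margin-fixed table probabilities share the denominator C(n, c1):
        # compare integer numerators exactly
        num_obs = comb(r1, a) * comb(n - r1, c1 - a)
        total = sum(
            num_x
            for x in range(lo, hi + 1)
            if (num_x := comb(r1, x) * comb(n - r1, c1 - x)) <= num_obs
        )
        p = total / comb(n, c1)
    if b * c == 0:
        odds = inf if a * d > 0 else nan
    else:
        odds = (a * d) / (b * c)
    return float(min(p, 1.0)), odds


def haldane_odds_ratio(table) -> float:
    """Haldane-Anscombe-corrected odds ratio (0.5 added to every cell)."""
    (a, b), (c, d) = table
    return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))


@dataclass(frozen=True)
class EnrichmentTestResult:
    """2x2 Fisher test of one bicluster against one tumor class."""

    bicluster_id: str
    target_tissue: str
    a: int  # in bicluster, target class
    b: int  # in bicluster, other
    c: int  # outside bicluster, target class
    d: int  # outside bicluster, other
    pvalue: float
    odds_ratio: float
    odds_ratio_haldane: float
    qvalue: float = nan


def cancer_enrichment_test(
    bicluster: Bicluster, samples: SampleTable, target_tissue: str
) -> EnrichmentTestResult:
    """Fisher test of bicluster membership vs membership in one tumor class.

    The table is built over all cohort samples, tumors and normals alike.
    """
    cohort = set(samples.table.index)
    unknown = bicluster.samples - cohort
    if unknown:
        raise ValueError(f"bicluster {bicluster.id}: unknown samples {sorted(unknown)[:5]}")
    target = set(samples.samples_of(tissue=target_tissue, condition="tumor"))
    if not target:
        raise ValueError(f"no tumor samples of tissue {target_tissue!r} in cohort")
    in_b = bicluster.samples
    a = len(in_b & target)
    b = len(in_b - target)
    c = len(target - in_b)
    d = len(cohort - in_b - target)
    p, odds = fisher_exact_2x2([[a, b], [c, d]])
    return EnrichmentTestResult(
        bicluster.id, target_tissue, a, b, c, d, p, odds, haldane_odds_ratio([[a, b], [c, d]])
    )


def select_cancer_specific(
    bset: BiclusterSet,
    samples: SampleTable,
    q_threshold: float = Q_THRESHOLD,
    tissues: tuple[str, ...] | None = None,
) -> tuple[BiclusterSet, dict[str, str], pd.DataFrame]:
    """Select biclusters enriched for one tumor class.

    Returns the selected subset, a bicluster-id -> enriched-tissue map, and
    the full test table.  q-values are BH-adjusted over all bicluster x class
    tests at once; selection requires q < ``q_threshold`` and odds ratio > 1
    for at least one class.  Ties in q between classes break toward the
    first tissue in ``tissues`` order.
    """
    tissues = tissues or samples.tissues
    results: list[EnrichmentTestResult] = []
    for bic in bset:
        for tissue in tissues:
            results.append(cancer_enrichment_test(bic, samples, tissue))
    if not results:
        return BiclusterSet([], source=bset.source), {}, pd.DataFrame()
    qvals = bh_adjust([r.pvalue for r in results])
    rows = []
    for r, q in zip(results, qvals):
        rows.append(
            {
                "bicluster": r.bicluster_id,
                "class": r.target_tissue,
                "a": r.a,
                "b": r.b,
                "c": r.c,
                "d": r.d,
                "pvalue": r.pvalue,
                "qvalue": q,
                "odds_ratio": r.odds_ratio,
                "odds_ratio_haldane": r.odds_ratio_haldane,
            }
        )
    table = pd.DataFrame(rows)
    selected: list[Bicluster] = []
    enriched_class: dict[str, str] = {}
    for bic in bset:
        sub = table[table["bicluster"] == bic.id]
        hits = sub[(sub["qvalue"] < q_threshold) & (sub["odds_ratio"] > 1)]
        if hits.empty:
            continue
        best_q = hits["qvalue"].min()
        best = hits[hits["qvalue"] == best_q]
        if len(best) > 1:
            logger.info("bicluster %s: class tie at q=%.3g, keeping first tissue", bic.id, best_q)
        klass = min(best["class"], key=lambda t: tissues.index(t))
        selected.append(bic)
        enriched_class[bic.id] = klass
    return BiclusterSet(selected, source=bset.source), enriched_class, table
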