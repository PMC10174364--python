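"""GO biological-process over-representation testing for gene sets.

One upper-tail hypergeometric test per term whose background annotation
count lies within configurable size bounds, Benjamini-Hochberg adjusted
within the query's family of tests.  Annotations must be propagated
(true-path rule) before testing.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .deg import GeneSet
from .ontology import OntologyDag, TermAnnotation

logger = logging.getLogger(__name__)

ENRICH_ALPHA = 0.05
MIN_TERM_SIZE = 3
MAX_TERM_SIZE = 2000


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent hypergeometric arguments k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_gene_set(
    query: GeneSet | Iterable[str],
    background: GeneSet | Iterable[str],
    annot: TermAnnotation,
    dag: OntologyDag,
    alpha: float = ENRICH_ALPHA,
    min_term: int = MIN_TERM_SIZE,
    max_term: int = MAX_TERM_SIZE,
) -> pd.DataFrame:
    """Over-representation table for ``query`` against ``background``.

    Rows: term, name, k (query hits), K (background hits), n (annotated
    query size), N (annotated background size), pvalue, padj, enriched.
    Query and background are intersected with the annotated gene universe;
    the query must be a subset of the background.
    """
    qset = set(query.genes if isinstance(query, GeneSet) else query)
    bset = set(background.genes if isinstance(background, GeneSet) else background)
    if not qset:
        raise ValueError("query gene set is empty")
    if not qset <= bset:
        raise ValueError(f"query genes missing from background: {sorted(qset - bset)[:5]}")
    if not annot.propagated:
        raise ValueError("annotations must be propagated before enrichment")
    annotated = {g for g in bset if annot.terms_of(g)}
    q_annot = qset & annotated
    N = len(annotated)
    n = len(q_annot)
    if n == 0:
        raise ValueError("no annotated query genes")
    term_K: dict[str, int] = {}
    term_k: dict[str, int] = {}
    for gene in annotated:
        in_query = gene in q_annot
        for term in annot.terms_of(gene):
            if term not in dag.terms:
                continue
            term_K[term] = term_K.get(term, 0) + 1
            if in_query:
                term_k[term] = term_k.get(term, 0) + 1
    rows = []
    for term, K in sorted(term_K.items()):
        if not (min_term <= K <= max_term):
            continue
        k = term_k.get(term, 0)
        rows.append(
            {
                "term": term,
                "name": dag.terms[term].name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "pvalue": hypergeom_upper_tail(k, K, n, N),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term", "name", "k", "K", "n", "N", "pvalue", "padj", "enriched"]
        )
    table = pd.DataFrame(rows)
    table["padj"] = bh_adjust(table["pvalue"].to_numpy())
    table["enriched"] = table["padj"] < alpha
    return table.sort_values("pvalue", kind="mergesort").reset_index(drop=True)


def enriched_terms(table: pd.DataFrame) -> frozenset[str]:
    """The term ids flagged enriched in an enrichment table."""
    if table.empty:
        return frozenset()
    return frozenset(table.loc[table["enriched"], "term"])
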