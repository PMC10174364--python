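"""Childness scoring of GO terms against a reference set of DEG-enriched terms.

A term's *childness* measures how far below the DEG-enriched region of the
ontology it sits:

    childness(t) = up(t) / (up(t) + down(t))

where ``up(t)`` is the maximum number of DEG terms lying on any directed
child-to-parent path starting at ``t`` (the query term itself excluded), and
``down(t)`` is the mirror count over descendant paths.  A term with DEG
ancestors but no DEG descendants scores 1; a term with no DEG relatives
scores 0.  Because the relation-restricted term graph is acyclic, both
counts are exact longest-weighted-path dynamic programs in O(V+E).

The term-set score of a bicluster is the arithmetic mean over its enriched
terms, and a gene's score is the maximum over its annotated terms.
Biclusters with a term-set score strictly above the threshold (default 0.6)
are deemed functionally relevant.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .ontology import CLOSURE_RELATIONS, OntologyDag, TermAnnotation

logger = logging.getLogger(__name__)

DEFAULT_CHILDNESS_THRESHOLD = 0.6


def _max_deg_count(
    dag: OntologyDag,
    term: str,
    deg_terms: frozenset[str],
    step,
    count_self: bool,
) -> int:
    """Longest DEG-weighted path from ``term`` via ``step`` (parents or children).

    Weight 1 is placed on every DEG term encountered past the query term;
    ``count_self`` additionally counts the query term itself when it is a
    DEG term.
    """
    memo: dict[str, int] = {}

    def best(node: str) -> int:
        # value = max over neighbours of (weight(neighbour) + best(neighbour)); 0 at sinks
        if node in memo:
            return memo[node]
        memo[node] = 0  # DAG: no cycles, placeholder never read back
        score = 0
        for nxt in step(node):
            cand = (1 if nxt in deg_terms else 0) + best(nxt)
            if cand > score:
                score = cand
        memo[node] = score
        return score

    base = best(term)
    if count_self and term in deg_terms:
        base += 1
    return base


def max_deg_count_up(
    dag: OntologyDag,
    term: str,
    deg_terms: Iterable[str],
    relations: Iterable[str] = CLOSURE_RELATIONS,
    count_self: bool = False,
) -> int:
    """Maximum number of DEG terms on any ancestor path of ``term``."""
    rel = frozenset(relations)
    dag._check(term)
    return _max_deg_count(dag, term, frozenset(deg_terms), lambda n: dag.parents(n, rel), count_self)


def max_deg_count_down(
    dag: OntologyDag,
    term: str,
    deg_terms: Iterable[str],
    relations: Iterable[str] = CLOSURE_RELATIONS,
    count_self: bool = False,
) -> int:
    """Maximum number of DEG terms on any descendant path of ``term``."""
    rel = frozenset(relations)
    dag._check(term)
    return _max_deg_count(dag, term, frozenset(deg_terms), lambda n: dag.children(n, rel), count_self)


def term_childness(
    dag: OntologyDag,
    term: str,
    deg_terms: Iterable[str],
    relations: Iterable[str] = CLOSURE_RELATIONS,
    count_self: bool = False,
) -> float:
    """up / (up + down); 0 when the term has no DEG relatives."""
    deg = frozenset(deg_terms)
    if not deg:
        logger.warning("term_childness called with an empty DEG term set")
        return 0.0
    up = max_deg_count_up(dag, term, deg, relations, count_self)
    down = max_deg_count_down(dag, term, deg, relations, count_self)
    if up + down == 0:
        return 0.0
    return up / (up + down)


def term_set_childness(
    dag: OntologyDag,
    terms: Iterable[str],
    deg_terms: Iterable[str],
    relations: Iterable[str] = CLOSURE_RELATIONS,
) -> float:
    """Arithmetic mean of term childness over a (nonempty) term set."""
    terms = list(terms)
    if not terms:
        raise ValueError("term_set_childness requires a nonempty term set")
    return float(np.mean([term_childness(dag, t, deg_terms, relations) for t in terms]))


def gene_childness(
    dag: OntologyDag,
    annot: TermAnnotation,
    gene: str,
    deg_terms: Iterable[str],
    relations: Iterable[str] = CLOSURE_RELATIONS,
) -> float:
    """Maximum term childness over a gene's annotated BP terms (0 if unannotated)."""
    terms = [t for t in annot.terms_of(gene) if t in dag.terms]
    if not terms:
        logger.warning("gene %r has no usable annotation; childness set to 0", gene)
        return 0.0
    return max(term_childness(dag, t, deg_terms, relations) for t in terms)


def select_functional_biclusters(
    scores: Mapping[str, float],
    threshold: float = DEFAULT_CHILDNESS_THRESHOLD,
) -> set[str]:
    """Bicluster ids whose term-set childness is strictly above ``threshold``."""
    return {bid for bid, score in scores.items() if score > threshold}


def compare_childness_groups(scores_a: Sequence[float], scores_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two score groups.

    Uses the exact null distribution when both groups have at most 20
    observations and there are no ties, and the normal approximation with
    continuity and tie corrections otherwise.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.pvalue)


@dataclass
class ChildnessReport:
    """Per-term, per-bicluster and per-gene childness scores vs a DEG term set."""

    deg_terms: frozenset[str]
    term_scores: dict[str, float] = field(default_factory=dict)
    term_updown: dict[str, tuple[int, int]] = field(default_factory=dict)
    set_scores: dict[str, float] = field(default_factory=dict)
    unscored_biclusters: list[str] = field(default_factory=list)
    gene_scores: dict[str, float] = field(default_factory=dict)
    threshold: float = DEFAULT_CHILDNESS_THRESHOLD

    def functional_biclusters(self) -> set[str]:
        return select_functional_biclusters(self.set_scores, self.threshold)

    def write_term_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("term\tup\tdown\tchildness\n")
            for term in sorted(self.term_scores):
                up, down = self.term_updown.get(term, (0, 0))
                fh.write(f"{term}\t{up}\t{down}\t{self.term_scores[term]:.6g}\n")

    def write_json(self, path) -> None:
        payload = {
            "deg_terms": sorted(self.deg_terms),
            "threshold": self.threshold,
            "term_set_childness": self.set_scores,
            "unscored_biclusters": self.unscored_biclusters,
            "functional_biclusters": sorted(self.functional_biclusters()),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def score_biclusters(
    dag: OntologyDag,
    enriched_terms: Mapping[str, Iterable[str]],
    deg_terms: Iterable[str],
    threshold: float = DEFAULT_CHILDNESS_THRESHOLD,
    relations: Iterable[str] = CLOSURE_RELATIONS,
) -> ChildnessReport:
    """Score each bicluster's enriched-term set against the DEG term set.

    ``enriched_terms`` maps bicluster id to its adjusted-P-significant BP
    terms.  Biclusters with no enriched terms are reported unscored rather
    than assigned 0.
    """
    deg = frozenset(deg_terms)
    report = ChildnessReport(deg_terms=deg, threshold=threshold)
    for bid, terms in enriched_terms.items():
        terms = [t for t in terms]
        if not terms:
            report.unscored_biclusters.append(bid)
            continue
        for t in terms:
            if t not in report.term_scores:
                up = max_deg_count_up(dag, t, deg, relations)
                down = max_deg_count_down(dag, t, deg, relations)
                report.term_updown[t] = (up, down)
                report.term_scores[t] = 0.0 if up + down == 0 else up / (up + down)
        report.set_scores[bid] = float(np.mean([report.term_scores[t] for t in terms]))
    return report
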