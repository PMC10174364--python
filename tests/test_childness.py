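import itertools

import numpy as np
import pytest

from bicfun.childness import (
    compare_childness_groups,
    gene_childness,
    max_deg_count_down,
    max_deg_count_up,
    score_biclusters,
    select_functional_biclusters,
    term_childness,
    term_set_childness,
)
from bicfun.ontology import CLOSURE_RELATIONS, TermAnnotation

from conftest import random_dag


def brute_force_max_count(dag, term, deg_terms, direction):
    """Enumerate every simple directed path and count DEG terms on it."""
    step = dag.parents if direction == "up" else dag.children
    best = 0

    def walk(node, count):
        nonlocal best
        best = max(best, count)
        for nxt in step(node, CLOSURE_RELATIONS):
            walk(nxt, count + (1 if nxt in deg_terms else 0))

    walk(term, 0)
    return best


class TestPathCounts:
    def test_chain_worked_examples(self, chain_dag):
        deg = {"A", "C"}
        assert max_deg_count_up(chain_dag, "D", deg) == 2
        assert max_deg_count_up(chain_dag, "A", deg) == 0
        assert max_deg_count_down(chain_dag, "A", deg) == 1
        assert max_deg_count_down(chain_dag, "D", deg) == 0
        assert max_deg_count_down(chain_dag, "B", {"C", "D"}) == 2

    def test_diamond_worked_example(self, diamond_dag):
        assert max_deg_count_up(diamond_dag, "D", {"B"}) == 1

    def test_unknown_term_raises(self, chain_dag):
        with pytest.raises(KeyError):
            max_deg_count_up(chain_dag, "nope", {"A"})

    def test_count_self_flag(self, chain_dag):
        assert max_deg_count_up(chain_dag, "C", {"C"}, count_self=True) == 1
        assert max_deg_count_up(chain_dag, "C", {"C"}) == 0

    def test_dp_equals_brute_force_on_random_dags(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            dag, names = random_dag(rng, max_terms=12)
            k = int(rng.integers(0, len(names) + 1))
            deg = set(rng.choice(names, size=k, replace=False).tolist())
            t = names[int(rng.integers(len(names)))]
            assert max_deg_count_up(dag, t, deg) == brute_force_max_count(dag, t, deg, "up")
            assert max_deg_count_down(dag, t, deg) == brute_force_max_count(dag, t, deg, "down")


class TestTermChildness:
    def test_chain_scores(self, chain_dag):
        deg = {"A", "C"}
        assert term_childness(chain_dag, "B", deg) == pytest.approx(0.5)
        assert term_childness(chain_dag, "D", deg) == pytest.approx(1.0)
        assert term_childness(chain_dag, "A", {"B"}) == 0.0  # only DEG descendants

    def test_no_deg_relatives_scores_zero(self, chain_dag):
        assert term_childness(chain_dag, "B", {"X_not_in_dag"}) == 0.0

    def test_empty_deg_set_warns_and_returns_zero(self, chain_dag):
        assert term_childness(chain_dag, "B", set()) == 0.0

    def test_bounds_and_extremes_on_random_dags(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            dag, names = random_dag(rng, max_terms=10)
            deg = {t for t in names if rng.random() < 0.4}
            for t in names:
                up = max_deg_count_up(dag, t, deg)
                down = max_deg_count_down(dag, t, deg)
                s = term_childness(dag, t, deg)
                assert 0.0 <= s <= 1.0
                assert (s == 1.0) == (up > 0 and down == 0)
                assert (s == 0.0) == (up == 0)

    def test_monotone_in_deg_ancestors_and_descendants(self, chain_dag):
        deg = {"C"}
        base = term_childness(chain_dag, "D", deg)
        with_extra_ancestor = term_childness(chain_dag, "D", deg | {"A"})
        assert with_extra_ancestor >= base
        base_b = term_childness(chain_dag, "B", {"A"})
        with_descendant = term_childness(chain_dag, "B", {"A", "D"})
        assert with_descendant <= base_b


class TestAggregateScores:
    def test_term_set_mean(self, chain_dag):
        deg = {"A", "C"}
        # childness(B) = 0.5, childness(D) = 1.0
        assert term_set_childness(chain_dag, ["B", "D"], deg) == pytest.approx(0.75)
        assert term_set_childness(chain_dag, ["D"], deg) == pytest.approx(1.0)

    def test_empty_term_set_errors(self, chain_dag):
        with pytest.raises(ValueError):
            term_set_childness(chain_dag, [], {"A"})

    def test_gene_childness_is_max_over_terms(self, chain_dag):
        annot = TermAnnotation({"g": frozenset({"B", "D"}), "r": frozenset({"A"})}, propagated=True)
        deg = {"A", "C"}
        assert gene_childness(chain_dag, annot, "g", deg) == pytest.approx(1.0)
        assert gene_childness(chain_dag, annot, "r", deg) == 0.0
        assert gene_childness(chain_dag, annot, "unannotated", deg) == 0.0

    def test_threshold_selection_is_strict(self):
        scores = {"b1": 0.7, "b2": 0.5, "b3": 0.6}
        assert select_functional_biclusters(scores, 0.6) == {"b1"}
        assert select_functional_biclusters({"b": 0.1}, 0.6) == set()

    def test_score_biclusters_reports_unscored(self, chain_dag):
        report = score_biclusters(chain_dag, {"b1": ["B", "D"], "b2": []}, {"A", "C"})
        assert report.set_scores["b1"] == pytest.approx(0.75)
        assert report.unscored_biclusters == ["b2"]
        assert "b2" not in report.set_scores


class TestWilcoxon:
    def test_exact_small_sample(self):
        # all 20 assignments of {1..6} into two triples; the observed split is
        # one of the two most extreme -> two-sided p = 2/20
        assert compare_childness_groups([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups_with_ties(self):
        assert compare_childness_groups([1, 2], [1, 2]) == pytest.approx(1.0)

    def test_single_elements_exact(self):
        assert compare_childness_groups([0.0], [1.0]) == pytest.approx(1.0)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            compare_childness_groups([], [1.0])

    def test_matches_explicit_enumeration(self):
        # independent oracle: enumerate all C(7,3) label assignments of the
        # pooled sample and compute the rank-sum tail probability
        a, b = [0.1, 0.9, 1.7], [0.4, 2.2, 3.1, 4.0]
        pooled = sorted(a + b)
        ranks = {v: i + 1 for i, v in enumerate(pooled)}
        obs = sum(ranks[v] for v in a)
        stats = [sum(ranks[pooled[i]] for i in comb) for comb in itertools.combinations(range(7), 3)]
        mean = np.mean(stats)
        p_exact = np.mean([abs(s - mean) >= abs(obs - mean) - 1e-12 for s in stats])
        assert compare_childness_groups(a, b) == pytest.approx(p_exact)
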