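import numpy as np
import pandas as pd
import pytest

from bicfun.biclustering import (
    Bicluster,
    BiclusterSet,
    bicluster_jaccard,
    combine_bicluster_sets,
    jaccard_matrix,
    normalize_for_biclustering,
    run_isa,
    run_plaid,
)
from bicfun.deg import size_factors
from bicfun.expression_io import ExpressionMatrix


def planted_frame(seed=0, shape=(50, 40), block=(10, 8), effect=5.0, noise=1.0):
    rng = np.random.default_rng(seed)
    Z = rng.normal(scale=noise, size=shape) if noise else np.zeros(shape)
    Z[: block[0], : block[1]] += effect
    return pd.DataFrame(
        Z, index=[f"g{i}" for i in range(shape[0])], columns=[f"s{j}" for j in range(shape[1])]
    )


class TestNormalize:
    def test_zscore_contract_and_constant_drop(self):
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(
            rng.poisson(50, size=(20, 6)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(6)],
        )
        counts.loc["flat"] = 0  # all-zero gene is constant after log-normalization
        m = ExpressionMatrix(counts)
        f = size_factors(m)
        norm = normalize_for_biclustering(m, f)
        assert "flat" not in norm.index
        assert np.abs(norm.mean(axis=1)).max() < 1e-10
        assert np.allclose(norm.std(axis=1, ddof=1), 1.0)

    def test_single_sample_errors(self):
        m = ExpressionMatrix(pd.DataFrame([[3]], index=["g"], columns=["s"]))
        with pytest.raises(ValueError):
            normalize_for_biclustering(m, pd.Series([1.0], index=["s"]))


class TestIsa:
    def test_planted_block_recovered_exactly(self):
        norm = planted_frame(seed=10)
        res = run_isa(norm, 2.0, 2.0, n_seeds=100, seed=7, initial_gene_size=20)
        truth_genes = frozenset(f"g{i}" for i in range(10))
        truth_samples = frozenset(f"s{j}" for j in range(8))
        assert any(b.genes == truth_genes and b.samples == truth_samples for b in res)

    def test_pure_noise_with_extreme_thresholds_is_empty(self):
        norm = planted_frame(seed=3, effect=0.0)
        res = run_isa(norm, 10.0, 10.0, n_seeds=50, seed=1)
        assert len(res) == 0

    def test_seed_determinism(self):
        norm = planted_frame(seed=4)
        a = run_isa(norm, 2.0, 2.0, n_seeds=50, seed=42)
        b = run_isa(norm, 2.0, 2.0, n_seeds=50, seed=42)
        assert [(x.genes, x.samples) for x in a] == [(x.genes, x.samples) for x in b]

    def test_fixed_point_invariant_to_reinitialization(self):
        norm = planted_frame(seed=10)
        res = run_isa(norm, 2.0, 2.0, n_seeds=100, seed=7, initial_gene_size=20)
        truth = next(b for b in res if b.genes == frozenset(f"g{i}" for i in range(10)))
        Z = norm.to_numpy()
        gmask = norm.index.isin(truth.genes)
        s_score = Z[gmask].mean(axis=0)
        smask = s_score > 2.0 * s_score.std()
        g_score = Z[:, smask].mean(axis=1)
        gmask2 = g_score > 2.0 * g_score.std()
        assert frozenset(norm.index[gmask2]) == truth.genes
        assert frozenset(norm.columns[smask]) == truth.samples

    def test_degenerate_matrix_errors(self):
        with pytest.raises(ValueError):
            run_isa(planted_frame().iloc[:1], 2.0, 2.0)


class TestPlaid:
    def test_single_planted_additive_block(self):
        norm = planted_frame(seed=5, noise=0.0)
        res = run_plaid(norm, max_layers=3, seed=9)
        assert len(res) >= 1
        first = res[0]
        assert first.genes == frozenset(f"g{i}" for i in range(10))
        assert first.samples == frozenset(f"s{j}" for j in range(8))

    def test_pure_noise_yields_no_layers(self):
        norm = planted_frame(seed=6, effect=0.0)
        res = run_plaid(norm, max_layers=3, seed=2)
        assert len(res) == 0

    def test_seed_determinism(self):
        norm = planted_frame(seed=8)
        a = run_plaid(norm, max_layers=2, seed=13)
        b = run_plaid(norm, max_layers=2, seed=13)
        assert [(x.genes, x.samples) for x in a] == [(x.genes, x.samples) for x in b]


class TestCombine:
    def _sets(self, sizes, source="50x40:aaaa"):
        out = []
        counter = 0
        for algo, size in sizes:
            bics = []
            for _ in range(size):
                counter += 1
                bics.append(
                    Bicluster(f"{algo}_{counter}", algo, frozenset({f"g{counter}"}), frozenset({"s"}))
                )
            out.append(BiclusterSet(bics, source=source))
        return out

    def test_published_per_algorithm_sizes_sum(self):
        sets = self._sets([("plaid", 2), ("qubic", 100), ("fabia", 13), ("isa", 38)])
        combined = combine_bicluster_sets(sets)
        assert len(combined) == 153
        assert len({b.id for b in combined}) == 153

    def test_empty_set_among_inputs(self):
        sets = self._sets([("isa", 3), ("plaid", 0), ("fabia", 2)])
        assert len(combine_bicluster_sets(sets)) == 5

    def test_duplicates_across_algorithms_retained(self):
        g, s = frozenset({"g"}), frozenset({"s"})
        a = BiclusterSet([Bicluster("x", "isa", g, s)], source="m")
        b = BiclusterSet([Bicluster("x2", "plaid", g, s)], source="m")
        assert len(combine_bicluster_sets([a, b])) == 2

    def test_mismatched_sources_error(self):
        a = self._sets([("isa", 1)], source="m1")[0]
        b = self._sets([("plaid", 1)], source="m2")[0]
        with pytest.raises(ValueError):
            combine_bicluster_sets([a, b])


class TestJaccard:
    def test_identity_and_disjoint(self):
        a = Bicluster("a", "isa", frozenset("ab"), frozenset("xy"))
        same = Bicluster("b", "plaid", frozenset("ab"), frozenset("xy"))
        disjoint = Bicluster("c", "isa", frozenset("cd"), frozenset("xy"))
        for mode in ("literal", "rectangles"):
            assert bicluster_jaccard(a, same, mode) == 1.0
            assert bicluster_jaccard(a, disjoint, mode) == 0.0

    def test_worked_literal_example(self):
        a = Bicluster("a", "isa", frozenset({"g1", "g2"}), frozenset({"s1", "s2"}))
        b = Bicluster("b", "isa", frozenset({"g2", "g3"}), frozenset({"s2", "s3"}))
        assert bicluster_jaccard(a, b, "literal") == pytest.approx(1 / 9)
        # rectangles: |A|=4, |B|=4, overlap 1 -> 1/7
        assert bicluster_jaccard(a, b, "rectangles") == pytest.approx(1 / 7)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(21)
        genes = [f"g{i}" for i in range(12)]
        samples = [f"s{i}" for i in range(10)]
        for _ in range(100):
            def rand_bic(i):
                g = rng.choice(genes, size=rng.integers(1, 8), replace=False)
                s = rng.choice(samples, size=rng.integers(1, 6), replace=False)
                return Bicluster(f"b{i}", "isa", frozenset(g), frozenset(s))

            a, b = rand_bic(0), rand_bic(1)
            j = bicluster_jaccard(a, b)
            assert 0.0 <= j <= 1.0
            assert j == bicluster_jaccard(b, a)
            assert (j == 1.0) == (a.genes == b.genes and a.samples == b.samples)

    def test_matrix_shape_and_equivariance(self):
        bics = [
            Bicluster("a", "isa", frozenset("ab"), frozenset("xy")),
            Bicluster("b", "isa", frozenset("ab"), frozenset("xy")),
            Bicluster("c", "isa", frozenset("cd"), frozenset("pq")),
        ]
        m = jaccard_matrix(BiclusterSet(bics))
        assert m.shape == (3, 3)
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(m, m.T)
        off = sorted([m.loc["a", "b"], m.loc["a", "c"], m.loc["b", "c"]])
        assert off == [0.0, 0.0, 1.0]
        perm = jaccard_matrix(BiclusterSet(bics[::-1]))
        assert perm.loc["a", "b"] == m.loc["a", "b"]

    def test_requires_two_biclusters(self):
        with pytest.raises(ValueError):
            jaccard_matrix(BiclusterSet([Bicluster("a", "isa", frozenset("a"), frozenset("x"))]))
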