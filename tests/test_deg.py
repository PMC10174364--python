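import numpy as np
import pandas as pd
import pytest

from bicfun._stats import bh_adjust
from bicfun.deg import (
    GeneSet,
    cancer_specific_degs,
    nb_deg_test,
    select_degs,
    size_factors,
)
from bicfun.expression_io import ExpressionMatrix


def nb_matrix(rng, n_genes, n_samples, mu=100.0, dispersion=0.1, ids=None):
    size = 1.0 / dispersion
    counts = rng.negative_binomial(size, size / (size + mu), size=(n_genes, n_samples))
    genes = [f"g{i}" for i in range(n_genes)]
    samples = ids or [f"s{i}" for i in range(n_samples)]
    return ExpressionMatrix(pd.DataFrame(counts, index=genes, columns=samples))


class TestSizeFactors:
    def test_proportional_columns(self):
        m = ExpressionMatrix(
            pd.DataFrame([[10, 20], [30, 60], [5, 10]], index=list("abc"), columns=["x", "y"])
        )
        f = size_factors(m)
        assert f["x"] == pytest.approx(1 / np.sqrt(2), abs=1e-4)
        assert f["y"] == pytest.approx(np.sqrt(2), abs=1e-4)

    def test_identical_columns_give_equal_factors(self):
        m = ExpressionMatrix(
            pd.DataFrame([[7, 7], [3, 3]], index=["a", "b"], columns=["x", "y"])
        )
        f = size_factors(m)
        assert f["x"] == pytest.approx(f["y"])

    def test_no_common_gene_errors_without_fallback(self):
        m = ExpressionMatrix(
            pd.DataFrame([[5, 0], [0, 5]], index=["a", "b"], columns=["x", "y"])
        )
        with pytest.raises(ValueError, match="pseudo"):
            size_factors(m)
        f = size_factors(m, allow_pseudo_reference=True)
        assert (f > 0).all()


class TestNbDegTest:
    def test_null_simulation_controls_error_rates(self):
        rng = np.random.default_rng(2024)
        m = nb_matrix(rng, 2000, 40)
        a, b = m.samples[:20], m.samples[20:]
        res = nb_deg_test(m, a, b)
        frac_raw = (res.table["pvalue"] < 0.05).mean()
        assert 0.03 <= frac_raw <= 0.07
        assert (res.table["padj"] < 1e-3).mean() <= 0.01

    def test_planted_fold_change_recovered(self):
        rng = np.random.default_rng(7)
        m = nb_matrix(rng, 500, 60)
        counts = m.counts.copy()
        # plant a 4-fold increase for the first 20 genes in the first 30 samples
        plant = rng.negative_binomial(10, 10 / (10 + 400.0), size=(20, 30))
        counts.iloc[:20, :30] = plant
        m2 = ExpressionMatrix(counts)
        res = nb_deg_test(m2, m.samples[:30], m.samples[30:])
        est = res.table["log2FoldChange"].iloc[:20].mean()
        assert est == pytest.approx(2.0, abs=0.2)

    def test_all_zero_genes_excluded_and_logged(self):
        rng = np.random.default_rng(1)
        m = nb_matrix(rng, 50, 8)
        counts = m.counts.copy()
        counts.iloc[0] = 0
        res = nb_deg_test(ExpressionMatrix(counts), m.samples[:4], m.samples[4:])
        assert "g0" in res.excluded_genes
        assert "g0" not in res.table.index

    def test_group_validation(self):
        rng = np.random.default_rng(3)
        m = nb_matrix(rng, 10, 6)
        with pytest.raises(ValueError, match="overlap"):
            nb_deg_test(m, m.samples[:3], m.samples[2:])
        with pytest.raises(ValueError, match="at least 2"):
            nb_deg_test(m, m.samples[:1], m.samples[3:])

    def test_direction_matches_fold_change_sign(self):
        rng = np.random.default_rng(11)
        m = nb_matrix(rng, 100, 20)
        res = nb_deg_test(m, m.samples[:10], m.samples[10:])
        t = res.table
        assert ((t["log2FoldChange"] >= 0) == (t["direction"] == "up")).all()
        assert (t["padj"] >= t["pvalue"] - 1e-15).all()


class TestBhAdjust:
    def test_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_and_degenerate_values(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert bh_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(5)
        p = rng.uniform(size=200)
        ours = bh_adjust(p)
        theirs = statsmodels.multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)


class TestSelection:
    def _table(self, rows):
        df = pd.DataFrame(
            rows, columns=["padj", "log2FoldChange"], index=[f"g{i}" for i in range(len(rows))]
        )
        df["pvalue"] = df["padj"]
        df["baseMean"] = 1.0
        df["direction"] = np.where(df["log2FoldChange"] >= 0, "up", "down")
        from bicfun.deg import DegTable

        return DegTable(df)

    def test_strict_thresholds(self):
        table = self._table([[0.0005, 1.5], [0.0005, 1.0], [0.01, 3.0], [0.0005, -1.2]])
        selected = select_degs(table)
        assert selected.genes == {"g0", "g3"}

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(8)
        table = self._table(
            [[p, l] for p, l in zip(rng.uniform(0, 0.01, 50), rng.normal(0, 2, 50))]
        )
        tight = select_degs(table, alpha=1e-3, min_abs_lfc=1.0)
        loose = select_degs(table, alpha=1e-2, min_abs_lfc=0.5)
        assert tight.genes <= loose.genes

    def test_empty_table(self):
        assert len(select_degs(self._table([]))) == 0


class TestCancerSpecific:
    def test_published_set_arithmetic(self):
        universe = [f"g{i}" for i in range(8000)]
        tumor = GeneSet("tumor", frozenset(universe[:5504]))
        # normal DEGs: 2438 shared with the tumor set plus 2144 others
        normal = GeneSet("normal", frozenset(universe[:2438]) | frozenset(universe[5504:7648]))
        result, venn = cancer_specific_degs(tumor, normal)
        assert venn == {
            "tumor": 5504,
            "normal": 4582,
            "intersection": 2438,
            "cancer_specific": 3066,
        }
        assert len(result) == 3066

    def test_disjoint_and_superset_cases(self):
        t = GeneSet("t", frozenset("abc"))
        assert cancer_specific_degs(t, GeneSet("n", frozenset("xyz")))[0].genes == set("abc")
        assert cancer_specific_degs(t, GeneSet("n", frozenset("abcd")))[0].genes == set()

    def test_size_identity(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(500)]
        t = GeneSet("t", frozenset(rng.choice(genes, 200, replace=False)))
        n = GeneSet("n", frozenset(rng.choice(genes, 150, replace=False)))
        result, venn = cancer_specific_degs(t, n)
        assert venn["cancer_specific"] == venn["tumor"] - venn["intersection"]
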