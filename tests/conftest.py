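import numpy as np
import pandas as pd
import pytest

from bicfun.ontology import OntologyDag, Term
from bicfun.expression_io import ExpressionMatrix, SampleTable
from bicfun.synthetic import GeneratorConfig, generate_cohort, generate_ontology


def make_dag(edges, namespace="biological_process"):
    """Build an OntologyDag from (child, parent, relation) triples."""
    terms = {}
    for c, p, r in edges:
        terms.setdefault(c, Term(c, c, namespace))
        terms.setdefault(p, Term(p, p, namespace))
    return OntologyDag(terms, edges, namespace=namespace)


@pytest.fixture(scope="session")
def chain_dag():
    """D is_a C is_a B is_a A."""
    return make_dag([("D", "C", "is_a"), ("C", "B", "is_a"), ("B", "A", "is_a")])


@pytest.fixture(scope="session")
def diamond_dag():
    """D below both B and C, which are both below A."""
    return make_dag(
        [("D", "B", "is_a"), ("D", "C", "part_of"), ("B", "A", "is_a"), ("C", "A", "is_a")]
    )


def random_dag(rng, max_terms=15, edge_prob=0.3):
    """Random layered DAG with mixed is_a/part_of edges (child -> parent)."""
    n = int(rng.integers(2, max_terms + 1))
    names = [f"T{i}" for i in range(n)]
    edges = []
    for i in range(1, n):
        # each node may attach to earlier nodes only: guarantees acyclicity
        parents = [j for j in range(i) if rng.random() < edge_prob]
        if not parents and i > 0:
            parents = [int(rng.integers(0, i))]
        for j in parents:
            rel = "part_of" if rng.random() < 0.3 else "is_a"
            edges.append((names[i], names[j], rel))
    return make_dag(edges), names


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down generator settings for fast unit tests."""
    return GeneratorConfig(
        n_genes=600,
        n_tumor_per_tissue=30,
        n_normal_per_tissue=45,
        n_tissue_de=60,
        n_cancer_de=60,
        module_genes=20,
        module_samples=12,
        normal_modules_per_tissue=2,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config, seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(GeneratorConfig(), seed=5)


@pytest.fixture(scope="session")
def default_ontology():
    return generate_ontology(GeneratorConfig(), seed=5)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default synthetic cohort, with truth."""
    from bicfun.expression_io import read_biclusters
    from bicfun.pipeline import PipelineConfig, run_pipeline, stage_seeds

    out = tmp_path_factory.mktemp("pipeline_default")
    config = PipelineConfig(simulate=GeneratorConfig(), seed=1)
    report = run_pipeline(config, out_dir=out)
    biclusters = read_biclusters(out / "biclusters.json")
    _, _, truth = generate_cohort(config.simulate, seed=stage_seeds(1)["cohort"])
    return report, biclusters, truth, out


@pytest.fixture()
def tiny_matrix():
    df = pd.DataFrame(
        [[10, 20], [30, 60], [5, 10]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )
    return ExpressionMatrix(df)


@pytest.fixture()
def six_sample_table():
    meta = pd.DataFrame(
        {
            "tissue": ["colon"] * 3 + ["endometrium"] * 3,
            "condition": ["tumor"] * 3 + ["normal"] * 3,
            "os_time": [100.0, 200.0, 300.0, np.nan, np.nan, np.nan],
            "os_event": [1, 0, 1, np.nan, np.nan, np.nan],
        },
        index=[f"s{i}" for i in range(6)],
    )
    return SampleTable(meta)
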