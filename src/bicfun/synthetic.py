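"""Synthetic two-tissue tumor/normal cohorts with planted ground truth.

The generator emulates the statistical structure the analysis assumes:

* two tissues (colon, endometrium) x tumor/normal groups, normals
  over-represented as in public compendia;
* tissue-DE genes, differentially expressed between the tissues in both
  tumors and normals (the confound the normal-DEG exclusion removes);
* cancer-DE genes, differentially expressed only between the two tumor
  classes;
* planted gene x sample modules: one cancer module per tumor class and
  several normal-tissue modules, each an additive log2 shift on a block;
* a toy GO BP tree in which cancer-module terms are descendants of the
  terms the cancer-DE genes annotate to ("DEG terms"), while tissue-DE
  genes and normal modules annotate to a disjoint decoy branch;
* exponential overall-survival times for tumor samples whose hazard is
  multiplied for members of a cancer module, with administrative censoring.

Counts are negative-binomial with constant dispersion.  Everything is
reproducible from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix, SampleTable
from .ontology import OntologyDag, Term, TermAnnotation

TISSUE_A = "colon"
TISSUE_B = "endometrium"


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    ``module_log2_effect`` is the additive shift on log2 mean expression for
    module cells; under the default baseline noise it realizes roughly
    +2.5 z-units in the per-gene standardized matrix while keeping the
    marginal tumor-contrast |log2FC| of module genes below 1.
    """

    n_genes: int = 2000
    n_tumor_per_tissue: int = 40
    n_normal_per_tissue: int = 60
    base_log2_mean: tuple[float, float] = (3.0, 9.0)
    dispersion: float = 0.1
    n_tissue_de: int = 150
    n_cancer_de: int = 150
    tissue_lfc: float = 2.0
    cancer_lfc: float = 1.2
    module_genes: int = 30
    module_samples: int = 15
    module_log2_effect: float = 1.6
    cancer_modules_per_tissue: int = 1
    normal_modules_per_tissue: int = 3
    ontology_depth: int = 4
    ontology_branching: int = 2
    part_of_fraction: float = 0.2
    baseline_hazard: float = 1.0 / 1500.0  # per day
    module_hazard_multiplier: float = 4.0
    censor_horizon_days: float = 1825.0

    def validate(self) -> None:
        if self.n_tumor_per_tissue < 2 or self.n_normal_per_tissue < 2:
            raise ValueError("each group needs at least 2 samples")
        if self.module_samples > self.n_tumor_per_tissue:
            raise ValueError("module_samples exceeds tumor group size")
        if self.normal_modules_per_tissue * self.module_samples > self.n_normal_per_tissue:
            raise ValueError("normal modules do not fit disjointly into the normal group")
        if self.cancer_modules_per_tissue * self.module_samples > self.n_tumor_per_tissue:
            raise ValueError("cancer modules do not fit disjointly into the tumor group")
        n_module_genes = self.module_genes * self.n_modules
        if self.n_tissue_de + self.n_cancer_de + n_module_genes > self.n_genes:
            raise ValueError("gene classes exceed the gene count")
        if self.ontology_depth < 3 or self.ontology_branching < 2:
            raise ValueError("ontology needs depth >= 3 and branching >= 2")
        leaves_per_branch = self.ontology_branching ** (self.ontology_depth - 1)
        if 2 * self.cancer_modules_per_tissue > leaves_per_branch:
            raise ValueError("not enough leaf terms under the DEG branch for cancer modules")
        if 2 * self.normal_modules_per_tissue > leaves_per_branch:
            raise ValueError("not enough leaf terms under the decoy branch for normal modules")
        for name in ("tissue_lfc", "cancer_lfc", "module_log2_effect"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    @property
    def n_modules(self) -> int:
        return 2 * (self.cancer_modules_per_tissue + self.normal_modules_per_tissue)

    def null(self) -> "GeneratorConfig":
        """The same cohort shape with every planted effect switched off."""
        return replace(
            self,
            tissue_lfc=0.0,
            cancer_lfc=0.0,
            module_log2_effect=0.0,
            module_hazard_multiplier=1.0,
        )


@dataclass(frozen=True)
class PlantedModule:
    name: str
    tissue: str
    condition: str
    genes: frozenset[str]
    samples: frozenset[str]
    term: str


@dataclass
class SyntheticTruth:
    """Planted structure of a generated cohort."""

    gene_classes: dict[str, str]
    modules: list[PlantedModule]
    deg_terms: frozenset[str]
    hazards: dict[str, float]

    def modules_of(self, condition: str) -> list[PlantedModule]:
        return [m for m in self.modules if m.condition == condition]

    def to_json(self, path) -> None:
        payload = {
            "gene_classes": self.gene_classes,
            "modules": [
                {
                    "name": m.name,
                    "tissue": m.tissue,
                    "condition": m.condition,
                    "genes": sorted(m.genes),
                    "samples": sorted(m.samples),
                    "term": m.term,
                }
                for m in self.modules
            ],
            "deg_terms": sorted(self.deg_terms),
            "hazards": self.hazards,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ----------------------------------------------------------------- fixed layout
def _gene_ids(config: GeneratorConfig) -> list[str]:
    width = len(str(config.n_genes - 1))
    return [f"g{i:0{width}d}" for i in range(config.n_genes)]


def _sample_ids(config: GeneratorConfig) -> dict[tuple[str, str], list[str]]:
    groups = {}
    for tissue in (TISSUE_A, TISSUE_B):
        groups[(tissue, "tumor")] = [
            f"{tissue}_tumor_{i:03d}" for i in range(config.n_tumor_per_tissue)
        ]
        groups[(tissue, "normal")] = [
            f"{tissue}_normal_{i:03d}" for i in range(config.n_normal_per_tissue)
        ]
    return groups


def _module_layout(config: GeneratorConfig) -> list[tuple[str, str, str]]:
    """(name, tissue, condition) for every planted module, in gene-block order."""
    layout = []
    for tissue in (TISSUE_A, TISSUE_B):
        for i in range(config.cancer_modules_per_tissue):
            layout.append((f"cancer_{tissue}_{i}", tissue, "tumor"))
    for tissue in (TISSUE_A, TISSUE_B):
        for i in range(config.normal_modules_per_tissue):
            layout.append((f"normal_{tissue}_{i}", tissue, "normal"))
    return layout


def _gene_classes(config: GeneratorConfig) -> dict[str, str]:
    genes = _gene_ids(config)
    classes: dict[str, str] = {}
    pos = 0
    half_t = config.n_tissue_de // 2
    for i in range(config.n_tissue_de):
        tissue = TISSUE_A if i < half_t else TISSUE_B
        classes[genes[pos]] = f"tissue_de_{tissue}"
        pos += 1
    half_c = config.n_cancer_de // 2
    for i in range(config.n_cancer_de):
        tissue = TISSUE_A if i < half_c else TISSUE_B
        classes[genes[pos]] = f"cancer_de_{tissue}"
        pos += 1
    for name, _, _ in _module_layout(config):
        for _ in range(config.module_genes):
            classes[genes[pos]] = f"module:{name}"
            pos += 1
    for g in genes[pos:]:
        classes[g] = "null"
    return classes


# --------------------------------------------------------------------- ontology
def _tree_nodes(config: GeneratorConfig) -> list[list[str]]:
    """Term ids by level (level 0 = root) of the complete b-ary tree."""
    levels = []
    counter = 0
    for depth in range(config.ontology_depth + 1):
        n = config.ontology_branching**depth
        levels.append([f"SYN:{counter + i:07d}" for i in range(n)])
        counter += n
    return levels


def generate_ontology(
    config: GeneratorConfig, seed: int | None = 0
) -> tuple[OntologyDag, TermAnnotation, frozenset[str]]:
    """Toy GO BP tree, gene annotations, and the designated DEG term set.

    The tree is a complete b-ary tree of the configured depth.  The children
    of the first depth-1 node are the "DEG terms" (annotated by cancer-DE
    genes); the children of the second depth-1 node are decoy terms
    (annotated by tissue-DE genes).  Cancer-module terms are leaves under
    the DEG branch, normal-module terms leaves under the decoy branch, so
    cancer modules -- and only they -- annotate to descendants of DEG terms.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    levels = _tree_nodes(config)
    b = config.ontology_branching
    terms: dict[str, Term] = {}
    edges: list[tuple[str, str, str]] = []
    for depth, level in enumerate(levels):
        for i, tid in enumerate(level):
            terms[tid] = Term(tid, f"synthetic term d{depth}n{i}", "biological_process")
            if depth > 0:
                parent = levels[depth - 1][i // b]
                relation = "part_of" if rng.random() < config.part_of_fraction else "is_a"
                edges.append((tid, parent, relation))
    dag = OntologyDag(terms, edges, namespace="biological_process")

    deg_terms = frozenset(levels[2][:b])  # children of the first depth-1 node
    decoy_terms = levels[2][b : 2 * b]
    module_terms = _module_terms(config)
    if len(set(module_terms.values())) != len(module_terms):
        raise ValueError("module term placement collided; increase depth or branching")

    classes = _gene_classes(config)
    deg_list = sorted(deg_terms)
    mapping: dict[str, frozenset[str]] = {}
    non_root = [t for level in levels[1:] for t in level]
    for gene, klass in classes.items():
        if klass.startswith("tissue_de_"):
            tissue = klass.removeprefix("tissue_de_")
            term = decoy_terms[0 if tissue == TISSUE_A else min(1, len(decoy_terms) - 1)]
        elif klass.startswith("cancer_de_"):
            tissue = klass.removeprefix("cancer_de_")
            term = deg_list[0 if tissue == TISSUE_A else min(1, len(deg_list) - 1)]
        elif klass.startswith("module:"):
            term = module_terms[klass.removeprefix("module:")]
        else:
            term = non_root[rng.integers(len(non_root))]
        mapping[gene] = frozenset({term})
    annot = TermAnnotation(mapping, propagated=False)
    return dag, annot, deg_terms


def _module_terms(config: GeneratorConfig) -> dict[str, str]:
    """Deterministic module-to-leaf-term placement (mirrors generate_ontology)."""
    levels = _tree_nodes(config)
    b = config.ontology_branching
    leaves = levels[-1]
    leaves_per_top = b ** (config.ontology_depth - 1)
    deg_leaves = leaves[:leaves_per_top]
    decoy_leaves = leaves[leaves_per_top : 2 * leaves_per_top]
    module_terms: dict[str, str] = {}
    cancer_i = normal_i = 0
    for name, _, condition in _module_layout(config):
        if condition == "tumor":
            step = max(1, leaves_per_top // (2 * config.cancer_modules_per_tissue))
            module_terms[name] = deg_leaves[(cancer_i * step) % leaves_per_top]
            cancer_i += 1
        else:
            step = max(1, leaves_per_top // (2 * config.normal_modules_per_tissue))
            module_terms[name] = decoy_leaves[(normal_i * step) % leaves_per_top]
            normal_i += 1
    return module_terms


# ----------------------------------------------------------------------- cohort
def generate_cohort(
    config: GeneratorConfig, seed: int | None = 0
) -> tuple[ExpressionMatrix, SampleTable, SyntheticTruth]:
    """Counts, sample metadata with survival, and the planted truth."""
    config.validate()
    rng = np.random.default_rng(seed)
    genes = _gene_ids(config)
    groups = _sample_ids(config)
    samples = [s for key in groups for s in groups[key]]
    sample_pos = {s: j for j, s in enumerate(samples)}
    classes = _gene_classes(config)

    log2mu = np.tile(
        rng.uniform(*config.base_log2_mean, size=config.n_genes)[:, None], (1, len(samples))
    )

    def cols(tissue=None, condition=None):
        out = []
        for (t, c), ids in groups.items():
            if (tissue is None or t == tissue) and (condition is None or c == condition):
                out.extend(sample_pos[s] for s in ids)
        return np.array(out)

    for i, g in enumerate(genes):
        klass = classes[g]
        if klass.startswith("tissue_de_"):
            log2mu[i, cols(tissue=klass.removeprefix("tissue_de_"))] += config.tissue_lfc
        elif klass.startswith("cancer_de_"):
            log2mu[i, cols(tissue=klass.removeprefix("cancer_de_"), condition="tumor")] += (
                config.cancer_lfc
            )

    # planted modules: disjoint sample blocks within each group, assigned from
    # a seeded permutation of the group's samples
    module_terms = _module_terms(config)
    block_cursor: dict[tuple[str, str], int] = {}
    perms: dict[tuple[str, str], list[str]] = {
        key: [groups[key][i] for i in rng.permutation(len(groups[key]))] for key in groups
    }
    modules: list[PlantedModule] = []
    module_gene_idx = {
        name: [i for i, g in enumerate(genes) if classes[g] == f"module:{name}"]
        for name, _, _ in _module_layout(config)
    }
    for name, tissue, condition in _module_layout(config):
        key = (tissue, condition)
        start = block_cursor.get(key, 0)
        chosen = perms[key][start : start + config.module_samples]
        block_cursor[key] = start + config.module_samples
        gidx = module_gene_idx[name]
        sidx = [sample_pos[s] for s in chosen]
        log2mu[np.ix_(gidx, sidx)] += config.module_log2_effect
        modules.append(
            PlantedModule(
                name=name,
                tissue=tissue,
                condition=condition,
                genes=frozenset(genes[i] for i in gidx),
                samples=frozenset(chosen),
                term=module_terms[name],
            )
        )

    mu = np.exp2(log2mu)
    size = 1.0 / config.dispersion
    counts = rng.negative_binomial(size, size / (size + mu)).astype(np.int64)
    matrix = ExpressionMatrix(pd.DataFrame(counts, index=genes, columns=samples))

    # survival: exponential with per-sample hazard, administrative censoring
    active: set[str] = set()
    for m in modules:
        if m.condition == "tumor":
            active |= set(m.samples)
    hazards: dict[str, float] = {}
    rows = []
    for (tissue, condition), ids in groups.items():
        for s in ids:
            row = {
                "sample": s,
                "tissue": tissue,
                "condition": condition,
                "msi": condition == "tumor",
                "cohort": "synthetic",
            }
            if condition == "tumor":
                rate = config.baseline_hazard * (
                    config.module_hazard_multiplier if s in active else 1.0
                )
                hazards[s] = rate
                t = rng.exponential(1.0 / rate)
                row["os_time"] = float(min(t, config.censor_horizon_days))
                row["os_event"] = int(t <= config.censor_horizon_days)
            else:
                row["os_time"] = np.nan
                row["os_event"] = np.nan
            rows.append(row)
    meta = pd.DataFrame(rows).set_index("sample")
    table = SampleTable(meta)

    levels = _tree_nodes(config)
    deg_terms = frozenset(levels[2][: config.ontology_branching])
    truth = SyntheticTruth(
        gene_classes=classes, modules=modules, deg_terms=deg_terms, hazards=hazards
    )
    return matrix, table, truth


def module_recovery(truth: SyntheticTruth, bset) -> dict[str, float]:
    """Best literal Jaccard of any found bicluster against each planted module."""
    from .biclustering import bicluster_jaccard, Bicluster

    out: dict[str, float] = {}
    for m in truth.modules:
        ref = Bicluster(id=f"truth_{m.name}", algorithm="truth", genes=m.genes, samples=m.samples)
        out[m.name] = max(
            (bicluster_jaccard(ref, b, mode="literal") for b in bset), default=0.0
        )
    return out
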