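"""End-to-end orchestration: DEG -> biclustering -> selection -> childness -> survival.

The workflow runs top to bottom:

1. tumor-contrast and normal-contrast differential expression, then
   exclusion of normal DEGs to obtain cancer-specific DEGs;
2. GO BP enrichment of the cancer-specific DEG set (the "DEG terms");
3. biclustering of the normalized matrix (ISA and/or Plaid), combined
   without deduplication;
4. Fisher-exact selection of cancer-class-enriched biclusters;
5. per-bicluster GO BP enrichment and term-set childness against the DEG
   terms; biclusters above the childness threshold are functionally
   relevant;
6. PCA-stratified Kaplan-Meier survival screen of the cancer-specific
   biclusters, and a Wilcoxon rank-sum comparison of childness between
   cancer-specific and other biclusters.

All randomness derives from a single master seed fanned out per stage.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biclustering import (
    BiclusterSet,
    combine_bicluster_sets,
    normalize_for_biclustering,
    run_isa,
    run_plaid,
)
from .childness import compare_childness_groups, score_biclusters
from .deg import GeneSet, cancer_specific_degs, nb_deg_test, select_degs, size_factors
from .enrichment import enrich_gene_set, enriched_terms
from .expression_io import read_counts, read_sample_table, write_biclusters
from .ontology import parse_obo, propagate_annotations, read_annotation_tsv
from .selection import select_cancer_specific
from .survival import SurvivalResult, bicluster_survival_screen
from .synthetic import GeneratorConfig, generate_cohort, generate_ontology

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and algorithm settings for one pipeline run.

    Threshold defaults match the published workflow: DEG adjusted P < 0.001
    with |log2FC| > 1, bicluster q < 0.001 with odds ratio > 1, enrichment
    adjusted P < 0.05, term-set childness > 0.6, survival alpha 0.05.
    """

    simulate: GeneratorConfig | None = None
    counts_path: str | None = None
    metadata_path: str | None = None
    obo_path: str | None = None
    annotation_path: str | None = None
    deg_alpha: float = 1e-3
    deg_min_abs_lfc: float = 1.0
    bicluster_q: float = 1e-3
    enrichment_alpha: float = 0.05
    childness_threshold: float = 0.6
    survival_alpha: float = 0.05
    algorithms: tuple[str, ...] = ("isa", "plaid")
    # cohort-scale ISA settings: single-gene seeding with many restarts and a
    # gene threshold strict enough to separate module cores from broad
    # class-level differential expression
    isa_n_seeds: int = 500
    isa_initial_gene_size: int = 1
    isa_gene_threshold: float = 3.5
    isa_sample_threshold: float = 2.0
    plaid_max_layers: int = 15
    seed: int = 0

    def validate(self) -> None:
        for name in ("deg_alpha", "bicluster_q", "enrichment_alpha", "survival_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not (0 <= self.childness_threshold <= 1):
            raise ValueError(
                f"childness_threshold must lie in [0, 1], got {self.childness_threshold}"
            )
        if self.deg_min_abs_lfc < 0:
            raise ValueError("deg_min_abs_lfc must be nonnegative")
        unknown = set(self.algorithms) - {"isa", "plaid"}
        if unknown:
            raise ValueError(f"unknown algorithms: {sorted(unknown)}")
        if self.simulate is None:
            required = (self.counts_path, self.metadata_path, self.obo_path, self.annotation_path)
            if any(p is None for p in required):
                raise ValueError("either a simulate block or all four input paths are required")


@dataclass
class PipelineReport:
    """Machine-readable summary of one pipeline run."""

    seed: int
    version: str
    n_tumor_degs: int = 0
    n_normal_degs: int = 0
    n_shared_degs: int = 0
    n_cancer_specific_degs: int = 0
    deg_terms: list[str] = field(default_factory=list)
    n_biclusters: int = 0
    n_cancer_specific_biclusters: int = 0
    n_functional_biclusters: int = 0
    n_survival_significant_functional: int = 0
    childness_wilcoxon_p: float | None = None
    per_bicluster: list[dict[str, Any]] = field(default_factory=list)
    config: dict[str, Any] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True, default=str)

    def functional_bicluster_ids(self) -> list[str]:
        return [r["id"] for r in self.per_bicluster if r.get("functional")]


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulate", None)
    cfg = PipelineConfig(**raw)
    if sim is not None:
        cfg.simulate = GeneratorConfig(**sim) if isinstance(sim, dict) else GeneratorConfig()
    if isinstance(cfg.algorithms, list):
        cfg.algorithms = tuple(cfg.algorithms)
    return cfg


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-22s %6.2fs", name, t1 - t0)
    return t1


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds fanned out from the master seed."""
    seeds = np.random.SeedSequence(master_seed).spawn(6)
    return {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(("cohort", "ontology", "isa", "plaid", "survival", "spare"), seeds)
    }


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineReport:
    """Execute the full workflow; deterministic given ``config.seed``."""
    config.validate()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    stage_seed = stage_seeds(config.seed)
    t0 = time.perf_counter()

    # ------------------------------------------------------------ inputs
    if config.simulate is not None:
        matrix, samples, truth = generate_cohort(config.simulate, seed=stage_seed["cohort"])
        dag, annot_raw, _ = generate_ontology(config.simulate, seed=stage_seed["ontology"])
    else:
        matrix = read_counts(config.counts_path)
        samples = read_sample_table(config.metadata_path)
        dag = parse_obo(config.obo_path)
        annot_raw = read_annotation_tsv(config.annotation_path)
        truth = None
    missing = set(samples.table.index) - set(matrix.samples)
    if missing:
        raise ValueError(f"metadata samples absent from matrix: {sorted(missing)[:5]}")
    annot = propagate_annotations(dag, annot_raw)
    t0 = _stage("inputs", t0)

    # ------------------------------------------------------------ DEG stage
    tissue_a, tissue_b = samples.tissues[0], samples.tissues[1]
    factors = size_factors(matrix)
    tumor_table = nb_deg_test(
        matrix,
        samples.samples_of(tissue_a, "tumor"),
        samples.samples_of(tissue_b, "tumor"),
        factors=factors,
    )
    normal_table = nb_deg_test(
        matrix,
        samples.samples_of(tissue_a, "normal"),
        samples.samples_of(tissue_b, "normal"),
        factors=factors,
    )
    tumor_degs = select_degs(tumor_table, config.deg_alpha, config.deg_min_abs_lfc, "tumor")
    normal_degs = select_degs(normal_table, config.deg_alpha, config.deg_min_abs_lfc, "normal")
    cancer_degs, venn = cancer_specific_degs(tumor_degs, normal_degs)
    t0 = _stage("deg", t0)

    # ------------------------------------------------ DEG-term enrichment
    background = GeneSet("background", frozenset(matrix.genes))
    if cancer_degs.genes:
        deg_enrich = enrich_gene_set(
            cancer_degs, background, annot, dag, alpha=config.enrichment_alpha
        )
        deg_terms = enriched_terms(deg_enrich)
    else:
        deg_enrich = pd.DataFrame()
        deg_terms = frozenset()
    t0 = _stage("deg-enrichment", t0)

    # --------------------------------------------------------- biclustering
    norm = normalize_for_biclustering(matrix, factors)
    per_algo: list[BiclusterSet] = []
    if "isa" in config.algorithms:
        per_algo.append(
            run_isa(
                norm,
                gene_threshold=config.isa_gene_threshold,
                sample_threshold=config.isa_sample_threshold,
                n_seeds=config.isa_n_seeds,
                seed=stage_seed["isa"],
                initial_gene_size=config.isa_initial_gene_size,
            )
        )
    if "plaid" in config.algorithms:
        per_algo.append(run_plaid(norm, max_layers=config.plaid_max_layers, seed=stage_seed["plaid"]))
    biclusters = combine_bicluster_sets(per_algo)
    t0 = _stage("biclustering", t0)

    # ------------------------------------------------- cancer-specific test
    selected, enriched_class, fisher_table = select_cancer_specific(
        biclusters, samples, q_threshold=config.bicluster_q
    )
    selected_ids = {b.id for b in selected}
    t0 = _stage("selection", t0)

    # ------------------------------------- per-bicluster enrichment + childness
    bic_terms: dict[str, frozenset[str]] = {}
    for bic in biclusters:
        query = frozenset(bic.genes) & set(matrix.genes)
        if not query:
            bic_terms[bic.id] = frozenset()
            continue
        table = enrich_gene_set(query, background, annot, dag, alpha=config.enrichment_alpha)
        bic_terms[bic.id] = enriched_terms(table)
    childness = score_biclusters(dag, bic_terms, deg_terms, threshold=config.childness_threshold)
    cancer_scores = {bid: s for bid, s in childness.set_scores.items() if bid in selected_ids}
    functional_ids = {
        bid for bid, s in cancer_scores.items() if s > config.childness_threshold
    }
    other_scores = [s for bid, s in childness.set_scores.items() if bid not in selected_ids]
    wilcoxon_p = None
    if cancer_scores and other_scores:
        wilcoxon_p = compare_childness_groups(list(cancer_scores.values()), other_scores)
    t0 = _stage("childness", t0)

    # ------------------------------------------------------------- survival
    survival_results: dict[str, SurvivalResult] = {}
    has_survival = (
        "os_time" in samples.table.columns
        and samples.table.loc[samples.table["condition"] == "tumor", "os_time"].notna().all()
    )
    if has_survival:
        for bic in selected:
            try:
                survival_results[bic.id] = bicluster_survival_screen(
                    bic,
                    norm,
                    samples,
                    enriched_class[bic.id],
                    alpha=config.survival_alpha,
                    seed=stage_seed["survival"],
                )
            except ValueError as exc:
                logger.warning("survival screen skipped for %s: %s", bic.id, exc)
    t0 = _stage("survival", t0)

    # --------------------------------------------------------------- report
    report = PipelineReport(seed=config.seed, version=__version__)
    report.n_tumor_degs = venn["tumor"]
    report.n_normal_degs = venn["normal"]
    report.n_shared_degs = venn["intersection"]
    report.n_cancer_specific_degs = venn["cancer_specific"]
    report.deg_terms = sorted(deg_terms)
    report.n_biclusters = len(biclusters)
    report.n_cancer_specific_biclusters = len(selected)
    report.n_functional_biclusters = len(functional_ids)
    report.childness_wilcoxon_p = wilcoxon_p
    n_sig = 0
    for bic in biclusters:
        rec: dict[str, Any] = {
            "id": bic.id,
            "algorithm": bic.algorithm,
            "n_genes": len(bic.genes),
            "n_samples": len(bic.samples),
            "cancer_specific": bic.id in selected_ids,
            "enriched_class": enriched_class.get(bic.id),
            "n_enriched_terms": len(bic_terms[bic.id]),
            "term_set_childness": childness.set_scores.get(bic.id),
            "functional": bic.id in functional_ids,
        }
        if not fisher_table.empty and bic.id in selected_ids:
            sub = fisher_table[
                (fisher_table["bicluster"] == bic.id)
                & (fisher_table["class"] == enriched_class[bic.id])
            ].iloc[0]
            rec["qvalue"] = float(sub["qvalue"])
            rec["odds_ratio"] = float(sub["odds_ratio"])
        sr = survival_results.get(bic.id)
        if sr is not None:
            rec["survival_p"] = sr.pvalues
            rec["survival_best_method"] = sr.best_method
            rec["survival_significant"] = sr.significant
            if bic.id in functional_ids and sr.significant:
                n_sig += 1
        report.per_bicluster.append(rec)
    report.n_survival_significant_functional = n_sig
    cfg = asdict(config)
    cfg["simulate"] = asdict(config.simulate) if config.simulate is not None else None
    report.config = cfg

    if out is not None:
        tumor_table.table.to_csv(out / "deg_tumor.tsv", sep="\t")
        normal_table.table.to_csv(out / "deg_normal.tsv", sep="\t")
        if not deg_enrich.empty:
            deg_enrich.to_csv(out / "deg_enrichment.tsv", sep="\t", index=False)
        write_biclusters(biclusters, out / "biclusters.json")
        if not fisher_table.empty:
            fisher_table.to_csv(out / "cancer_specific_tests.tsv", sep="\t", index=False)
        childness.write_term_tsv(out / "childness_terms.tsv")
        childness.write_json(out / "childness.json")
        report.to_json(out / "report.json")
    return report
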