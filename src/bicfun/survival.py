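"""PCA-stratified Kaplan-Meier screening of biclusters for prognostic value.

For a bicluster with an enriched cancer class, expression of the bicluster
genes is taken over *all* tumor samples of that class (not only bicluster
members), samples are split into two groups by the median of PC1 or PC2 or
by k-means (k=2) on the first two principal components, and the two groups
are compared with a two-group log-rank test on overall survival.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .biclustering import Bicluster
from .expression_io import SampleTable

logger = logging.getLogger(__name__)

SURVIVAL_ALPHA = 0.05
STRATIFICATION_METHODS = ("pc1-median", "pc2-median", "kmeans2")


def pca_stratify(expr: pd.DataFrame, method: str, seed: int | None = None) -> pd.Series:
    """Two-group sample labels from PCA of bicluster-gene expression.

    ``expr`` is genes x samples.  Genes are standardized, PCA treats samples
    as observations.  Median splits assign values equal to the median to the
    "low" group; ``kmeans2`` clusters the first two PCs with 10 restarts.
    """
    if method not in STRATIFICATION_METHODS:
        raise ValueError(f"unknown stratification method {method!r}")
    if expr.shape[1] < 4:
        raise ValueError("need at least 4 samples to stratify")
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 genes to stratify")
    X = expr.to_numpy(dtype=float).T  # samples x genes
    sd = X.std(axis=0)
    if not (sd > 0).any():
        raise ValueError("constant expression matrix")
    keep = sd > 0
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    n_comp = min(2, X.shape[0] - 1, X.shape[1])
    pcs = PCA(n_components=n_comp, svd_solver="full").fit_transform(X)
    if method in ("pc1-median", "pc2-median"):
        axis = 0 if method == "pc1-median" else 1
        if axis >= pcs.shape[1]:
            raise ValueError("second principal component unavailable")
        vals = pcs[:, axis]
        labels = np.where(vals > np.median(vals), "high", "low")
    else:
        km = KMeans(n_clusters=2, n_init=10, random_state=None if seed is None else int(seed) % (2**31))
        labels = np.where(km.fit_predict(pcs[:, : min(2, pcs.shape[1])]) == 0, "c1", "c2")
    if len(set(labels)) < 2:
        raise ValueError("stratification produced a single group")
    return pd.Series(labels, index=expr.columns, name=method)


def km_curve(times, events) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier product-limit estimate as (event time, survival) step pairs.

    Censored times reduce the risk set without adding steps.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if (times < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter().fit(times, events)
    event_times = np.unique(times[events == 1])
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    return event_times, surv


def logrank_test(times, events, labels) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p) with 1 df."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(groups)}")
    mask = labels == groups[0]
    if not mask.any() or mask.all():
        raise ValueError("each group needs at least one subject")
    if events.sum() == 0:
        return 0.0, 1.0
    res = _ll_logrank(times[mask], times[~mask], events[mask], events[~mask])
    stat = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(stat):
        return 0.0, 1.0
    return stat, p


@dataclass
class SurvivalResult:
    """Per-bicluster survival screen across the three stratification methods."""

    bicluster_id: str
    cohort: str
    pvalues: dict[str, float]
    statistics: dict[str, float]
    labels: dict[str, dict[str, str]]
    alpha: float = SURVIVAL_ALPHA
    km_curves: dict[str, dict[str, tuple[list[float], list[float]]]] = field(default_factory=dict)

    @property
    def best_method(self) -> str:
        return min(self.pvalues, key=self.pvalues.get)

    @property
    def significant(self) -> bool:
        return any(p < self.alpha for p in self.pvalues.values())


def bicluster_survival_screen(
    bicluster: Bicluster,
    norm: pd.DataFrame,
    samples: SampleTable,
    target_tissue: str,
    alpha: float = SURVIVAL_ALPHA,
    seed: int | None = None,
) -> SurvivalResult:
    """Run all three PCA stratifications and log-rank tests for one bicluster.

    Expression is restricted to the bicluster genes crossed with *all* tumor
    samples of the enriched class; the bicluster is flagged significant when
    any method reaches p < ``alpha``.
    """
    cohort = samples.samples_of(tissue=target_tissue, condition="tumor")
    if not cohort:
        raise ValueError(f"no tumor samples for tissue {target_tissue!r}")
    missing = bicluster.genes - set(norm.index)
    if missing:
        raise ValueError(f"bicluster genes absent from matrix: {sorted(missing)[:5]}")
    expr = norm.loc[sorted(bicluster.genes), cohort]
    times, events = samples.survival_of(cohort)
    pvals: dict[str, float] = {}
    stat_map: dict[str, float] = {}
    label_map: dict[str, dict[str, str]] = {}
    curves: dict[str, dict[str, tuple[list[float], list[float]]]] = {}
    for method in STRATIFICATION_METHODS:
        labels = pca_stratify(expr, method, seed=seed)
        stat, p = logrank_test(times, events, labels.to_numpy())
        pvals[method] = p
        stat_map[method] = stat
        label_map[method] = labels.to_dict()
        per_group = {}
        for g in np.unique(labels.to_numpy()):
            m = labels.to_numpy() == g
            t, s = km_curve(times[m], events[m])
            per_group[str(g)] = (t.tolist(), s.tolist())
        curves[method] = per_group
    return SurvivalResult(
        bicluster_id=bicluster.id,
        cohort=target_tissue,
        pvalues=pvals,
        statistics=stat_map,
        labels=label_map,
        alpha=alpha,
        km_curves=curves,
    )
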