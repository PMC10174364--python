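"""Biclustering of normalized expression: ISA and Plaid, plus pair-based Jaccard.

Both algorithms operate on the log-normalized, per-gene z-scored matrix
produced by :func:`normalize_for_biclustering`.

ISA alternates thresholded scoring of samples (over the current gene set)
and genes (over the current sample set) from many random initial gene sets
until a fixed point; the membership rule keeps entries whose score exceeds
``threshold`` times the standard deviation of the score vector.  Scores are
signed; this implementation tracks up-modules (the planted-signal
orientation of z-scored data).

Plaid peels additive layers mu + alpha_i + beta_j off the residual matrix.
A row (column) is kept in a layer while the layer model explains at least
``release_threshold`` of its sum of squares within the layer's columns
(rows); each layer must beat the 95th percentile of layer sums of squares
obtained on column-permuted residual matrices to be retained.

Additional algorithms plug in through :data:`ALGORITHMS` or by importing
bicluster JSON written by external tools (see
:func:`bicfun.expression_io.read_biclusters`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .expression_io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Bicluster:
    """A gene-set x sample-set pair with algorithm provenance."""

    id: str
    algorithm: str
    genes: frozenset[str]
    samples: frozenset[str]

    def __post_init__(self):
        if not self.genes or not self.samples:
            raise ValueError(f"bicluster {self.id}: gene and sample sets must be nonempty")

    def key(self) -> tuple[frozenset[str], frozenset[str]]:
        return (self.genes, self.samples)


@dataclass
class BiclusterSet:
    """Ordered collection of (possibly overlapping) biclusters."""

    biclusters: list[Bicluster] = field(default_factory=list)
    source: str = ""

    def __post_init__(self):
        ids = [b.id for b in self.biclusters]
        if len(set(ids)) != len(ids):
            raise ValueError("bicluster ids must be unique")

    def __len__(self) -> int:
        return len(self.biclusters)

    def __iter__(self):
        return iter(self.biclusters)

    def __getitem__(self, i):
        return self.biclusters[i]

    def by_id(self, bid: str) -> Bicluster:
        for b in self.biclusters:
            if b.id == bid:
                return b
        raise KeyError(bid)


def _source_signature(norm: pd.DataFrame) -> str:
    return f"{norm.shape[0]}x{norm.shape[1]}:{hash((tuple(norm.index), tuple(norm.columns))) & 0xFFFFFFFF:08x}"


def normalize_for_biclustering(
    matrix: ExpressionMatrix, factors: pd.Series
) -> pd.DataFrame:
    """log2(count/size_factor + 1), then per-gene z-score; constant genes dropped."""
    counts = matrix.counts
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples to z-score genes")
    logged = np.log2(counts.to_numpy(dtype=float) / factors.loc[counts.columns].to_numpy() + 1.0)
    sd = logged.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        logger.info("normalize_for_biclustering: dropping %d constant genes", int((~keep).sum()))
    z = (logged[keep] - logged[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return pd.DataFrame(z, index=counts.index[keep], columns=counts.columns)


# --------------------------------------------------------------------------- ISA
def run_isa(
    norm: pd.DataFrame,
    gene_threshold: float = 2.0,
    sample_threshold: float = 2.0,
    n_seeds: int = 100,
    seed: int | None = None,
    initial_gene_size: int = 20,
    max_iter: int = 100,
) -> BiclusterSet:
    """Iterative signature algorithm; deterministic given ``seed``.

    Each random initial gene set is iterated to a fixed point; non-converged
    seeds are discarded and duplicate fixed points merged.
    """
    if norm.shape[0] < 2 or norm.shape[1] < 2:
        raise ValueError("matrix must have at least 2 genes and 2 samples")
    if gene_threshold <= 0 or sample_threshold <= 0:
        raise ValueError("thresholds must be positive")
    Z = norm.to_numpy(dtype=float)
    n_genes, n_samples = Z.shape
    rng = np.random.default_rng(seed)
    found: dict[tuple[frozenset[int], frozenset[int]], None] = {}
    order: list[tuple[frozenset[int], frozenset[int]]] = []
    init_size = min(initial_gene_size, n_genes)
    for _ in range(n_seeds):
        gene_mask = np.zeros(n_genes, dtype=bool)
        gene_mask[rng.choice(n_genes, size=init_size, replace=False)] = True
        prev: tuple[frozenset[int], frozenset[int]] | None = None
        converged = None
        for _ in range(max_iter):
            s_score = Z[gene_mask].mean(axis=0)
            s_sd = s_score.std()
            if s_sd == 0:
                break
            sample_mask = s_score > sample_threshold * s_sd
            if not sample_mask.any():
                break
            g_score = Z[:, sample_mask].mean(axis=1)
            g_sd = g_score.std()
            if g_sd == 0:
                break
            new_gene_mask = g_score > gene_threshold * g_sd
            if not new_gene_mask.any():
                break
            state = (
                frozenset(np.flatnonzero(new_gene_mask).tolist()),
                frozenset(np.flatnonzero(sample_mask).tolist()),
            )
            if prev is not None and state == prev:
                converged = state
                break
            prev = state
            gene_mask = new_gene_mask
        if converged is not None and converged not in found:
            found[converged] = None
            order.append(converged)
    biclusters = []
    for i, (gset, sset) in enumerate(order, start=1):
        biclusters.append(
            Bicluster(
                id=f"isa_{i}",
                algorithm="isa",
                genes=frozenset(norm.index[sorted(gset)]),
                samples=frozenset(norm.columns[sorted(sset)]),
            )
        )
    return BiclusterSet(biclusters, source=_source_signature(norm))


# ------------------------------------------------------------------------- Plaid
def _fit_layer(R: np.ndarray, release: float, max_iter: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit one additive layer on the residual matrix.

    Returns boolean row/column membership masks and the fitted layer values
    mu + alpha_i + beta_j for the members (empty masks when no coherent
    layer is found).
    """
    n_rows, n_cols = R.shape
    # seed memberships from the leading singular vectors of the residual
    try:
        U, s, Vt = np.linalg.svd(R, full_matrices=False)
    except np.linalg.LinAlgError:  # pragma: no cover - pathological input
        return np.zeros(n_rows, bool), np.zeros(n_cols, bool), np.zeros((0, 0))
    u, v = U[:, 0], Vt[0]
    # orient so the dominant block is positive
    if np.abs(u.min()) > np.abs(u.max()):
        u, v = -u, -v
    rows = u > 0.5 * u.max() if u.max() > 0 else np.zeros(n_rows, bool)
    cols = v > 0.5 * v.max() if v.max() > 0 else np.zeros(n_cols, bool)
    if rows.sum() < 2 or cols.sum() < 2:
        return np.zeros(n_rows, bool), np.zeros(n_cols, bool), np.zeros((0, 0))
    empty = (np.zeros(n_rows, bool), np.zeros(n_cols, bool), np.zeros((0, 0)))
    for _ in range(max_iter):
        # row update: fitted_ij = alpha_i + (mu + beta_j), with mu+beta_j taken
        # as the column means over the current member rows; a row stays while
        # the fit explains >= `release` of its sum of squares on the columns
        colpart = R[np.ix_(rows, cols)].mean(axis=0)
        Rc = R[:, cols]
        alpha_all = Rc.mean(axis=1) - colpart.mean()
        fitted = alpha_all[:, None] + colpart[None, :]
        sse = ((Rc - fitted) ** 2).sum(axis=1)
        sst = (Rc**2).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            new_rows = (sst > 0) & (1.0 - sse / sst >= release)
        if new_rows.sum() < 2:
            return empty
        # column update, mirror image using the refreshed rows
        rowpart = R[np.ix_(new_rows, cols)].mean(axis=1)
        Rr = R[new_rows, :]
        beta_all = Rr.mean(axis=0) - rowpart.mean()
        fitted_c = rowpart[:, None] + beta_all[None, :]
        sse_c = ((Rr - fitted_c) ** 2).sum(axis=0)
        sst_c = (Rr**2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            new_cols = (sst_c > 0) & (1.0 - sse_c / sst_c >= release)
        if new_cols.sum() < 2:
            return empty
        if np.array_equal(new_rows, rows) and np.array_equal(new_cols, cols):
            break
        rows, cols = new_rows, new_cols
    if rows.sum() < 2 or cols.sum() < 2:
        return np.zeros(n_rows, bool), np.zeros(n_cols, bool), np.zeros((0, 0))
    sub = R[np.ix_(rows, cols)]
    mu = sub.mean()
    theta = mu + (sub.mean(axis=1) - mu)[:, None] + (sub.mean(axis=0) - mu)[None, :]
    return rows, cols, theta


def run_plaid(
    norm: pd.DataFrame,
    max_layers: int = 10,
    seed: int | None = None,
    n_permutations: int = 20,
    release_threshold: float = 0.7,
    max_iter: int = 10,
) -> BiclusterSet:
    """Plaid layer model; layers gated by a column-permutation significance test."""
    if norm.shape[0] < 2 or norm.shape[1] < 2:
        raise ValueError("matrix must have at least 2 genes and 2 samples")
    rng = np.random.default_rng(seed)
    R = norm.to_numpy(dtype=float).copy()
    biclusters = []
    for layer_idx in range(1, max_layers + 1):
        rows, cols, theta = _fit_layer(R, release_threshold, max_iter)
        if not rows.any():
            break
        ss = float((theta**2).sum())
        perm_ss = []
        for _ in range(n_permutations):
            P = R.copy()
            for j in range(P.shape[1]):
                P[:, j] = P[rng.permutation(P.shape[0]), j]
            pr, pc, ptheta = _fit_layer(P, release_threshold, max_iter)
            perm_ss.append(float((ptheta**2).sum()) if pr.any() else 0.0)
        if ss <= float(np.quantile(perm_ss, 0.95)):
            break
        biclusters.append(
            Bicluster(
                id=f"plaid_{layer_idx}",
                algorithm="plaid",
                genes=frozenset(norm.index[rows]),
                samples=frozenset(norm.columns[cols]),
            )
        )
        R[np.ix_(rows, cols)] -= theta
    return BiclusterSet(biclusters, source=_source_signature(norm))


#: Registry for biclustering back-ends; external tools plug in here.
ALGORITHMS: dict[str, Callable[..., BiclusterSet]] = {"isa": run_isa, "plaid": run_plaid}


def combine_bicluster_sets(sets: Sequence[BiclusterSet]) -> BiclusterSet:
    """Concatenate per-algorithm results with fresh unique ids (no deduplication)."""
    sources = {s.source for s in sets if s.source}
    if len(sources) > 1:
        raise ValueError("bicluster sets derive from different source matrices")
    combined = []
    for i, b in enumerate((b for s in sets for b in s), start=1):
        combined.append(Bicluster(id=f"bc_{i}", algorithm=b.algorithm, genes=b.genes, samples=b.samples))
    return BiclusterSet(combined, source=next(iter(sources), ""))


def bicluster_jaccard(a: Bicluster, b: Bicluster, mode: str = "literal") -> float:
    """Pair-based Jaccard similarity between two biclusters.

    ``literal`` treats the intersection/union of the (gene, sample) pair sets
    as products of the set intersections/unions; ``rectangles`` computes the
    union as the union of the two rectangles.
    """
    gi = len(a.genes & b.genes)
    si = len(a.samples & b.samples)
    inter = gi * si
    if mode == "literal":
        union = len(a.genes | b.genes) * len(a.samples | b.samples)
    elif mode == "rectangles":
        union = len(a.genes) * len(a.samples) + len(b.genes) * len(b.samples) - inter
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return inter / union if union else 0.0


def jaccard_matrix(
    bset: BiclusterSet, mode: str = "literal", ordering: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, list[str]]:
    """Symmetric unit-diagonal Jaccard matrix; optional average-linkage display order."""
    if len(bset) < 2:
        raise ValueError("need at least 2 biclusters")
    ids = [b.id for b in bset]
    n = len(ids)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = bicluster_jaccard(bset[i], bset[j], mode)
    df = pd.DataFrame(mat, index=ids, columns=ids)
    if not ordering:
        return df
    dist = squareform(1.0 - mat, checks=False)
    leaves = hierarchy.leaves_list(hierarchy.average(dist))
    return df, [ids[i] for i in leaves]
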