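"""Readers and writers for count matrices, sample metadata, and bicluster JSON."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

if TYPE_CHECKING:  # pragma: no cover
    from .biclustering import BiclusterSet

logger = logging.getLogger(__name__)

TISSUES = ("colon", "endometrium")
CONDITIONS = ("tumor", "normal")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample raw counts with an optional normalized layer.

    Counts must be nonnegative integers; gene and sample ids are opaque,
    unique strings.
    """

    counts: pd.DataFrame
    normalized: pd.DataFrame | None = None

    def __post_init__(self):
        c = self.counts
        if c.index.duplicated().any():
            dupes = c.index[c.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if c.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            frac, _ = np.modf(vals.astype(float))
            bad = np.argwhere(frac != 0)
            if bad.size:
                i, j = bad[0]
                raise ValueError(
                    f"non-integer count at gene {c.index[i]!r}, sample {c.columns[j]!r}"
                )
            self.counts = c.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValueError(f"negative count at gene {c.index[i]!r}, sample {c.columns[j]!r}")
        if self.normalized is not None and self.normalized.shape[1] != c.shape[1]:
            raise ValueError("normalized layer has inconsistent sample dimension")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class SampleTable:
    """Per-sample labels and survival fields.

    Required columns: ``tissue`` and ``condition``.  ``os_time`` (days) and
    ``os_event`` (0/1) are required for tumor samples and may be missing for
    normals.  Optional: ``msi`` flag and a free-form ``cohort`` label.
    """

    table: pd.DataFrame
    tissues: tuple[str, ...] = TISSUES

    def __post_init__(self):
        t = self.table
        for col in ("tissue", "condition"):
            if col not in t.columns:
                raise ValueError(f"sample table missing required column {col!r}")
        if t.index.duplicated().any():
            raise ValueError("duplicate sample ids in sample table")
        bad_tissue = set(t["tissue"]) - set(self.tissues)
        if bad_tissue:
            raise ValueError(f"unknown tissue level(s): {sorted(bad_tissue)}")
        bad_cond = set(t["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValueError(f"unknown condition level(s): {sorted(bad_cond)}")
        tumors = t[t["condition"] == "tumor"]
        if "os_event" in t.columns or "os_time" in t.columns:
            time = tumors.get("os_time", pd.Series(np.nan, index=tumors.index))
            event = tumors.get("os_event", pd.Series(np.nan, index=tumors.index))
            if (event.notna() & time.isna()).any():
                sid = tumors.index[(event.notna() & time.isna())][0]
                raise ValueError(f"tumor sample {sid!r} has an event flag but no survival time")
            if (pd.to_numeric(time.dropna()) < 0).any():
                raise ValueError("negative survival time")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_samples(self) -> int:
        return len(self.table)

    def samples_of(self, tissue: str | None = None, condition: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        if tissue is not None:
            mask &= self.table["tissue"] == tissue
        if condition is not None:
            mask &= self.table["condition"] == condition
        return list(self.table.index[mask])

    def survival_of(self, sample_ids: Iterable[str]) -> tuple[np.ndarray, np.ndarray]:
        sub = self.table.loc[list(sample_ids)]
        if "os_time" not in sub.columns or sub["os_time"].isna().any():
            missing = [] if "os_time" not in sub.columns else list(sub.index[sub["os_time"].isna()])
            raise ValueError(f"samples without survival data: {missing[:5] or 'os_time column absent'}")
        return (
            sub["os_time"].to_numpy(dtype=float),
            sub["os_event"].to_numpy(dtype=int),
        )


def read_counts(path, format: str | None = None) -> ExpressionMatrix:
    """Read a count matrix from TSV or MatrixMarket.

    TSV: header row of sample ids, first column gene ids.  MTX: coordinate
    file plus ``<stem>.genes.txt`` and ``<stem>.samples.txt`` sidecars (one
    id per line).
    """
    path = Path(path)
    fmt = format or ("mtx" if path.suffix == ".mtx" else "tsv")
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return ExpressionMatrix(df)
    if fmt == "mtx":
        genes_path = path.with_suffix(".genes.txt")
        samples_path = path.with_suffix(".samples.txt")
        for sidecar in (genes_path, samples_path):
            if not sidecar.exists():
                raise FileNotFoundError(f"missing MatrixMarket sidecar: {sidecar}")
        mat = spio.mmread(path)
        genes = genes_path.read_text().split()
        samples = samples_path.read_text().split()
        dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
        if dense.shape != (len(genes), len(samples)):
            raise ValueError("MatrixMarket dimensions do not match sidecar ids")
        return ExpressionMatrix(pd.DataFrame(dense, index=genes, columns=samples))
    raise ValueError(f"unknown format {fmt!r}")


def write_counts(matrix: ExpressionMatrix, path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="gene")


def read_sample_table(path, tissues: tuple[str, ...] = TISSUES) -> SampleTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SampleTable(df, tissues=tissues)


def write_sample_table(samples: SampleTable, path) -> None:
    samples.table.to_csv(path, sep="\t", index_label="sample")


def write_biclusters(bset: "BiclusterSet", path) -> None:
    """Serialize a bicluster set as a JSON list of {id, algorithm, genes, samples}."""
    payload = [
        {
            "id": b.id,
            "algorithm": b.algorithm,
            "genes": sorted(b.genes),
            "samples": sorted(b.samples),
        }
        for b in bset
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def read_biclusters(path, matrix: ExpressionMatrix | None = None) -> "BiclusterSet":
    """Read bicluster JSON; optionally validate membership against a matrix."""
    from .biclustering import Bicluster, BiclusterSet

    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    if not isinstance(payload, list):
        raise ValueError("bicluster JSON must be a list")
    biclusters = []
    for rec in payload:
        b = Bicluster(
            id=str(rec["id"]),
            algorithm=str(rec.get("algorithm", "external")),
            genes=frozenset(rec["genes"]),
            samples=frozenset(rec["samples"]),
        )
        if matrix is not None:
            missing_g = b.genes - set(matrix.genes)
            missing_s = b.samples - set(matrix.samples)
            if missing_g or missing_s:
                raise ValueError(
                    f"bicluster {b.id}: unknown genes {sorted(missing_g)[:3]} "
                    f"or samples {sorted(missing_s)[:3]}"
                )
        biclusters.append(b)
    return BiclusterSet(biclusters)
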