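"""Domain containers and on-disk formats.

Expression data are held genes x observations (cells or pixels); the
orientation is fixed at ingest and never guessed. Identifiers, not positions,
are the external contract: coordinate and annotation files are aligned to the
expression matrix by observation id on read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class ExpressionMatrix:
    """A nonnegative gene-by-observation count matrix with unique ids."""

    counts: np.ndarray  # genes x observations, dense float array
    gene_ids: list[str]
    obs_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2D matrix")
        n_genes, n_obs = self.counts.shape
        if n_genes < 1 or n_obs < 1:
            raise ValidationError("need at least 1 gene and 1 observation")
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.obs_ids) != n_obs:
            raise ValidationError(
                f"{len(self.obs_ids)} obs ids for {n_obs} matrix columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("gene ids must be unique")
        if len(set(self.obs_ids)) != n_obs:
            raise ValidationError("observation ids must be unique")
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("counts contain NaN or infinite entries")
        if np.any(self.counts < 0):
            raise ValidationError("counts contain negative entries")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_obs(self) -> int:
        return self.counts.shape[1]


@dataclass
class SpatialTranscriptome:
    """ST reference: expression plus a 2D coordinate per pixel."""

    expr: ExpressionMatrix
    coords: np.ndarray  # pixels x 2

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError("coords must be pixels x 2")
        if self.coords.shape[0] != self.expr.n_obs:
            raise ValidationError(
                f"{self.coords.shape[0]} coordinate rows for "
                f"{self.expr.n_obs} pixels"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coords must be finite")


@dataclass
class QueryCells:
    """SC query: expression plus optional per-cell type annotations."""

    expr: ExpressionMatrix
    annotations: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.annotations is not None:
            unknown = set(self.annotations) - set(self.expr.obs_ids)
            if unknown:
                raise ValidationError(
                    f"annotation keys not in obs ids: {sorted(unknown)[:5]}"
                )


def _dedupe(names: list[str]) -> list[str]:
    """De-duplicate symbols by suffixing .1, .2, ... (first occurrence kept)."""
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}.{seen[name]}")
        else:
            seen[name] = 0
            out.append(name)
    return out


def read_expression(path: str | Path, format: str = "dense_csv") -> ExpressionMatrix:
    """Read a gene x observation count matrix.

    ``mtx_dir`` expects a directory with ``matrix.mtx``, ``features.tsv``
    (gene ids in the first column) and ``barcodes.tsv``; ``dense_csv`` expects
    genes as rows, observations as columns, with header and index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such path: {path}")
    if format == "mtx_dir":
        mtx = path / "matrix.mtx"
        features = path / "features.tsv"
        barcodes = path / "barcodes.tsv"
        for f in (mtx, features, barcodes):
            if not f.exists():
                raise FileNotFoundError(f"mtx_dir missing {f.name}")
        counts = np.asarray(scipy.io.mmread(mtx).todense(), dtype=float)
        gene_ids = pd.read_csv(features, sep="\t", header=None)[0].astype(str).tolist()
        obs_ids = pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str).tolist()
    elif format == "dense_csv":
        sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        counts = df.to_numpy(dtype=float)
        gene_ids = [str(g) for g in df.index]
        obs_ids = [str(o) for o in df.columns]
    else:
        raise ValueError(f"unknown format {format!r}")
    deduped = _dedupe(gene_ids)
    if deduped != gene_ids:
        logger.warning("duplicate gene symbols de-duplicated by suffixing")
    return ExpressionMatrix(counts=counts, gene_ids=deduped, obs_ids=obs_ids)


def write_expression_mtx(expr: ExpressionMatrix, out_dir: str | Path) -> None:
    """Write matrix.mtx / features.tsv / barcodes.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(expr.counts)
    scipy.io.mmwrite(out / "matrix.mtx", sparse)
    (out / "features.tsv").write_text("\n".join(expr.gene_ids) + "\n")
    (out / "barcodes.tsv").write_text("\n".join(expr.obs_ids) + "\n")


def read_coordinates(path: str | Path, expr: ExpressionMatrix) -> np.ndarray:
    """Read ``obs_id,x,y`` CSV, reordered to the expression observation order.

    Every expression observation must appear exactly once; unknown extra rows
    are ignored with a warning.
    """
    df = pd.read_csv(path)
    required = {"obs_id", "x", "y"}
    if not required <= set(df.columns):
        raise ValidationError(f"coordinate CSV must have columns {sorted(required)}")
    df["obs_id"] = df["obs_id"].astype(str)
    dup = df["obs_id"][df["obs_id"].duplicated()].tolist()
    if dup:
        raise ValidationError(f"duplicate obs ids in coordinates: {dup[:5]}")
    lookup = df.set_index("obs_id")
    missing = [o for o in expr.obs_ids if o not in lookup.index]
    if missing:
        raise ValidationError(f"coordinates missing obs ids: {missing[:5]}")
    extra = set(lookup.index) - set(expr.obs_ids)
    if extra:
        logger.warning("ignoring %d unknown obs rows in coordinates", len(extra))
    return lookup.loc[expr.obs_ids, ["x", "y"]].to_numpy(dtype=float)


def read_annotations(path: str | Path) -> dict[str, str]:
    """Read an ``obs_id,label`` CSV into a mapping."""
    df = pd.read_csv(path)
    if not {"obs_id", "label"} <= set(df.columns):
        raise ValidationError("annotation CSV must have columns obs_id,label")
    return dict(zip(df["obs_id"].astype(str), df["label"].astype(str)))


def write_reconstruction(graph, layout, out_dir: str | Path, metadata: dict | None = None) -> None:
    """Write an SMN reconstruction: edge list, node table and run metadata.

    Edge list is tab-separated ``node_a<TAB>node_b``; the node table is a CSV
    with ``id,type,x,y,z``. Refuses an empty graph and mismatched node sets.
    """
    nodes = list(graph.nodes)
    if not nodes:
        raise ValidationError("refusing to write an empty reconstruction")
    if set(layout.node_ids) != set(nodes):
        raise ValidationError("layout nodes do not match graph nodes")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "edges.tsv", "w") as fh:
        for a, b in sorted(graph.edges):
            fh.write(f"{a}\t{b}\n")
    pos = {n: layout.coords[i] for i, n in enumerate(layout.node_ids)}
    labels = graph.node_labels or {}
    rows = [
        {
            "id": n,
            "type": labels.get(n, ""),
            "x": pos[n][0],
            "y": pos[n][1],
            "z": pos[n][2],
        }
        for n in nodes
    ]
    pd.DataFrame(rows).to_csv(out / "nodes.csv", index=False)
    meta = dict(metadata or {})
    meta.setdefault("k_requested", graph.k_requested)
    with open(out / "metadata.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_reconstruction(out_dir: str | Path):
    """Re-read a written reconstruction; returns (SMNGraph, Layout3D, metadata)."""
    from .smn import SMNGraph, Layout3D

    out = Path(out_dir)
    nodes_df = pd.read_csv(out / "nodes.csv", keep_default_na=False)
    edges = []
    with open(out / "edges.tsv") as fh:
        for line in fh:
            a, b = line.rstrip("\n").split("\t")
            edges.append((a, b))
    with open(out / "metadata.yaml") as fh:
        meta = yaml.safe_load(fh)
    node_ids = [str(n) for n in nodes_df["id"]]
    labels = {
        str(r["id"]): str(r["type"]) for _, r in nodes_df.iterrows() if r["type"] != ""
    }
    graph = SMNGraph(
        node_ids=node_ids,
        edges={frozenset(e) for e in edges},
        k_requested=int(meta.get("k_requested", 0) or 0),
        node_labels=labels or None,
    )
    layout = Layout3D(
        coords=nodes_df[["x", "y", "z"]].to_numpy(dtype=float),
        node_ids=node_ids,
        seed=int(meta.get("seed", 0) or 0),
    )
    return graph, layout, meta
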