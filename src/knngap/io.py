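"""Readers and writers: Matrix Market droplet layout, dense delimited text,
and run-result tables."""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .preprocess import CountMatrix

log = logging.getLogger(__name__)

_GENE_FILES = ("genes.tsv", "features.tsv", "genes.txt")
_BARCODE_FILES = ("barcodes.tsv", "barcodes.txt")


def _read_label_column(path: Path) -> np.ndarray:
    """First column of a single/multi-column text file (10x genes/barcodes)."""
    labels = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                labels.append(line.split("\t")[0].split(",")[0])
    return np.asarray(labels, dtype=object)


def _find_companion(mtx_path: Path, names) -> Path:
    for name in names:
        cand = mtx_path.parent / name
        if cand.exists():
            return cand
    raise FileNotFoundError(
        f"no companion file among {names} next to {mtx_path}"
    )


def read_mtx(path, genes_path=None, barcodes_path=None) -> CountMatrix:
    """Matrix Market counts (genes as rows) with gene/barcode label files.

    ``path`` may be the .mtx file or a directory containing matrix.mtx.
    """
    path = Path(path)
    if path.is_dir():
        mtx = path / "matrix.mtx"
        if not mtx.exists():
            raise FileNotFoundError(f"{path} does not contain matrix.mtx")
    else:
        mtx = path
    matrix = scipy.io.mmread(mtx)
    if sp.issparse(matrix):
        matrix = matrix.toarray()
    genes = _read_label_column(Path(genes_path) if genes_path else _find_companion(mtx, _GENE_FILES))
    barcodes = _read_label_column(
        Path(barcodes_path) if barcodes_path else _find_companion(mtx, _BARCODE_FILES)
    )
    if genes.size != matrix.shape[0]:
        raise ValueError(
            f"gene file has {genes.size} entries but matrix has {matrix.shape[0]} rows"
        )
    if barcodes.size != matrix.shape[1]:
        raise ValueError(
            f"barcode file has {barcodes.size} entries but matrix has {matrix.shape[1]} columns"
        )
    return CountMatrix(counts=matrix, gene_ids=genes, cell_ids=barcodes)


def read_dense(path, cells_in_rows: bool = False) -> CountMatrix:
    """Dense delimited text: header row of cell ids, first column gene ids."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if cells_in_rows:
        df = df.T
    return CountMatrix(
        counts=df.to_numpy(),
        gene_ids=df.index.to_numpy(dtype=object),
        cell_ids=df.columns.to_numpy(dtype=object),
    )


def read_matrix(path, dialect: str = "auto", cells_in_rows: bool = False,
                genes_path=None, barcodes_path=None) -> CountMatrix:
    """Dispatch on dialect: 'mtx', 'dense' or 'auto' (by extension)."""
    path = Path(path)
    if dialect == "auto":
        if path.is_dir() or path.suffix.lower() == ".mtx":
            dialect = "mtx"
        else:
            dialect = "dense"
    if dialect == "mtx":
        return read_mtx(path, genes_path=genes_path, barcodes_path=barcodes_path)
    if dialect == "dense":
        return read_dense(path, cells_in_rows=cells_in_rows)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_mtx(counts: CountMatrix, out_dir, labels=None) -> Path:
    """Write matrix.mtx + genes.tsv + barcodes.tsv (+ labels.tsv) to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out_dir / "matrix.mtx"), sp.coo_matrix(counts.counts))
    (out_dir / "genes.tsv").write_text("\n".join(counts.gene_ids) + "\n")
    (out_dir / "barcodes.tsv").write_text("\n".join(counts.cell_ids) + "\n")
    if labels is not None:
        with open(out_dir / "labels.tsv", "w") as fh:
            fh.write("cell_id\tgroup\n")
            for c, g in zip(counts.cell_ids, labels):
                fh.write(f"{c}\t{g}\n")
    return out_dir


def write_dense(counts: CountMatrix, path) -> Path:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    pd.DataFrame(counts.counts, index=counts.gene_ids, columns=counts.cell_ids).to_csv(
        path, sep=sep
    )
    return path


def write_result(result, cell_ids, out_dir, config=None) -> Path:
    """Persist a run: per-cell table, cluster summary, resolved config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cell_ids = np.asarray(cell_ids, dtype=object)
    pd.DataFrame(
        {
            "cell_id": cell_ids,
            "label": ["none" if not l else l for l in result.per_cell_label],
            "score": result.per_cell_score,
        }
    ).to_csv(out_dir / "cells.tsv", sep="\t", index=False)
    summary = {
        "n_clusters": len(result.clusters),
        "clusters": [
            {
                "id": f"R{i + 1}",
                "size_k": int(c.size_k),
                "skewness": float(c.skewness_value),
                "top_cell": str(cell_ids[c.top_cell]),
                "members": [str(cell_ids[m]) for m in c.member_cells],
            }
            for i, c in enumerate(result.clusters)
        ],
        "parameters": {k: _jsonable(v) for k, v in result.parameters.items()},
    }
    with open(out_dir / "clusters.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    if config is not None:
        with open(out_dir / "config.json", "w") as fh:
            json.dump({k: _jsonable(v) for k, v in vars(config).items()}, fh, indent=2)
    return out_dir


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, Path):
        return str(v)
    return v
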