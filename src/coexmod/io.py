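"""Reading and writing the 10x-style MatrixMarket triple.

On disk: ``matrix.mtx[.gz]`` in MatrixMarket coordinate integer format with
1-based indices and genes as rows, ``features.tsv[.gz]`` and
``barcodes.tsv[.gz]`` label files, and an optional ``cell_meta.tsv`` keyed
by barcode.  In memory the matrix is 0-based CSR (see
:class:`~coexmod.containers.CountMatrix`).
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CELL_META_COLUMNS, CountMatrix

__all__ = ["read_10x_mtx", "write_10x_mtx"]


def _open_maybe_gz(path: Path, mode: str = "rt"):
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _find(dir_path: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dir_path / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}[.gz] not found in {dir_path}")


def write_10x_mtx(cm: CountMatrix, dir_path, gzip_files: bool = False) -> Path:
    """Write a CountMatrix as matrix.mtx + features.tsv + barcodes.tsv
    (+ cell_meta.tsv)."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if gzip_files else ""

    mtx_path = dir_path / f"matrix.mtx{suffix}"
    coo = cm.counts.tocoo()
    with _open_maybe_gz(mtx_path, "wt") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write(f"{cm.n_genes} {cm.n_cells} {coo.nnz}\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i + 1} {j + 1} {int(v)}\n")

    feat = pd.DataFrame({
        "gene_id": cm.gene_ids,
        "gene_name": cm.gene_ids,
        "feature_type": "Gene Expression",
    })
    feat.to_csv(dir_path / f"features.tsv{suffix}", sep="\t",
                header=False, index=False)
    pd.Series(cm.cell_ids).to_csv(dir_path / f"barcodes.tsv{suffix}",
                                  sep="\t", header=False, index=False)
    cm.cell_meta.rename_axis("barcode").to_csv(
        dir_path / "cell_meta.tsv", sep="\t")
    return dir_path


def read_10x_mtx(dir_path) -> CountMatrix:
    """Load matrix.mtx[.gz] + features + barcodes (+ cell_meta) from a dir.

    Cross-checks matrix dimensions against the label files, converts the
    1-based on-disk indices to the internal 0-based convention, and enforces
    integer counts and unique identifiers.
    """
    dir_path = Path(dir_path)
    mtx_path = _find(dir_path, "matrix.mtx")
    with _open_maybe_gz(mtx_path, "rb" if mtx_path.suffix == ".gz" else "rb") \
            as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.csr_matrix(mat)
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise ValueError(f"{mtx_path}: non-integer values in count matrix")
    mat = mat.astype(np.int64)

    features = pd.read_csv(_find(dir_path, "features.tsv"), sep="\t",
                           header=None)
    barcodes = pd.read_csv(_find(dir_path, "barcodes.tsv"), sep="\t",
                           header=None)
    gene_ids = features.iloc[:, 0].astype(str).to_numpy(dtype=object)
    cell_ids = barcodes.iloc[:, 0].astype(str).to_numpy(dtype=object)
    if len(gene_ids) != mat.shape[0]:
        raise ValueError(
            f"dimension mismatch: matrix has {mat.shape[0]} rows but "
            f"features.tsv lists {len(gene_ids)} genes"
        )
    if len(cell_ids) != mat.shape[1]:
        raise ValueError(
            f"dimension mismatch: matrix has {mat.shape[1]} columns but "
            f"barcodes.tsv lists {len(cell_ids)} barcodes"
        )
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene identifiers in features.tsv")
    if len(set(cell_ids)) != len(cell_ids):
        raise ValueError("duplicate barcodes in barcodes.tsv")

    meta_path = dir_path / "cell_meta.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
        meta = meta.reindex(cell_ids)
        if meta.isna().all(axis=1).any():
            raise ValueError("cell_meta.tsv missing rows for some barcodes")
    else:
        meta = pd.DataFrame(
            {c: "unknown" for c in CELL_META_COLUMNS},
            index=pd.Index(cell_ids),
        )
    meta.index = pd.Index(cell_ids)
    return CountMatrix(counts=mat, gene_ids=gene_ids, cell_ids=cell_ids,
                       cell_meta=meta)
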