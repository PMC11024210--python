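"""Reading and writing the pipeline's on-disk formats.

Count matrices travel as a MatrixMarket triplet directory
(``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``, 1-based indices per
the format) or as a dense CSV with cells in rows; clone and ortholog
tables as TSV with headers.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp


def write_counts(adata: ad.AnnData, path: str | Path) -> None:
    """Write an MTX triplet directory (genes in rows, cells in columns)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    sio.mmwrite(str(path / "matrix.mtx"), X.T.tocoo(), field="integer")
    pd.Series(adata.var_names).to_csv(path / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
    if len(adata.obs.columns):
        adata.obs.to_csv(path / "obs.tsv", sep="\t")


def read_counts(path: str | Path) -> ad.AnnData:
    """Read counts from an MTX triplet directory or a dense CSV file."""
    path = Path(path)
    if path.is_dir():
        mtx = path / "matrix.mtx"
        if not mtx.exists():
            raise FileNotFoundError(f"no matrix.mtx under {path}")
        X = sio.mmread(str(mtx)).T.tocsr()
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].astype(str)
        barcodes_path = path / "barcodes.tsv"
        if barcodes_path.stat().st_size > 0:
            barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str)
        else:
            barcodes = pd.Series([], dtype=str)
        if X.shape != (len(barcodes), len(genes)):
            raise ValueError(
                f"matrix shape {X.shape} does not match {len(barcodes)} barcodes x {len(genes)} genes"
            )
        obs = pd.DataFrame(index=pd.Index(barcodes, name="cell_id"))
        obs_path = path / "obs.tsv"
        if obs_path.exists():
            obs = pd.read_csv(obs_path, sep="\t", index_col=0)
            obs.index = obs.index.astype(str)
        adata = ad.AnnData(
            X=X.astype(np.int64),
            obs=obs,
            var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
        )
        return adata
    df = pd.read_csv(path, index_col=0)
    return ad.AnnData(
        X=sp.csr_matrix(df.to_numpy(dtype=np.int64)),
        obs=pd.DataFrame(index=pd.Index(df.index.astype(str), name="cell_id")),
        var=pd.DataFrame(index=pd.Index(df.columns.astype(str), name="gene_id")),
    )


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
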