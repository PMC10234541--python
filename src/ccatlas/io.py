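"""Dataset loading and saving.

On-disk layout follows the droplet-pipeline convention: a Matrix Market file
with genes in rows and cells in columns, `genes.tsv` / `barcodes.tsv`
sidecars, and a `metadata.tsv` keyed by cell id with columns patient,
condition, cell_type and cell_subtype. A dense CSV (genes in rows, header =
cell ids) is accepted as an alternative. In memory everything is an AnnData
with cells in obs and genes in var.
"""

from __future__ import annotations

import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = ["load_dataset", "save_dataset", "load_lr_table", "REQUIRED_METADATA_COLUMNS"]

logger = logging.getLogger(__name__)

REQUIRED_METADATA_COLUMNS = ("patient", "condition", "cell_type", "cell_subtype")


def _deduplicate(names: list[str], what: str) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for n in names:
        if n in seen:
            seen[n] += 1
            new = f"{n}.{seen[n]}"
            logger.warning("duplicate %s symbol %r renamed to %r", what, n, new)
            out.append(new)
        else:
            seen[n] = 0
            out.append(n)
    return out


def load_dataset(counts_path, metadata_path) -> ad.AnnData:
    """Read counts (MTX + sidecars, or dense CSV) and per-cell metadata.

    MTX is interpreted genes x cells and transposed; `genes.tsv` and
    `barcodes.tsv` must sit next to the matrix file. Dense CSV has genes in
    rows with the header naming cells. The metadata TSV/CSV must carry a
    cell_id column (or index) plus patient, condition, cell_type and
    cell_subtype; cells present in the counts but absent from the metadata are
    an error listing the offenders.
    """
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        mat = spio.mmread(counts_path)
        genes = pd.read_csv(counts_path.parent / "genes.tsv", sep="\t", header=None)[0].tolist()
        cells = pd.read_csv(counts_path.parent / "barcodes.tsv", sep="\t", header=None)[0].tolist()
        X = np.asarray(sparse.coo_matrix(mat).todense(), dtype=np.float64).T
    else:
        frame = pd.read_csv(counts_path, index_col=0)
        genes = frame.index.tolist()
        cells = frame.columns.tolist()
        X = frame.to_numpy(dtype=np.float64).T
    if X.shape != (len(cells), len(genes)):
        raise ValueError(
            f"matrix shape {X.shape} does not match {len(genes)} genes x {len(cells)} cells"
        )
    genes = _deduplicate(genes, "gene")

    sep = "\t" if str(metadata_path).endswith((".tsv", ".txt")) else ","
    meta = pd.read_csv(metadata_path, sep=sep)
    key = "cell_id" if "cell_id" in meta.columns else meta.columns[0]
    meta = meta.set_index(key)
    missing_cols = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata missing required column(s): {missing_cols}")
    absent = [c for c in cells if c not in meta.index]
    if absent:
        raise ValueError(f"{len(absent)} cell(s) absent from metadata, e.g. {absent[:5]}")
    obs = meta.loc[cells, list(REQUIRED_METADATA_COLUMNS)].copy()
    obs.index.name = "cell_id"
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))


def save_dataset(adata: ad.AnnData, out_dir) -> dict[str, Path]:
    """Write matrix.mtx (genes x cells, integer field when counts are whole),
    genes.tsv, barcodes.tsv and metadata.tsv into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    X = np.asarray(adata.X)
    mat = sparse.coo_matrix(X.T)
    integer = np.allclose(mat.data, np.round(mat.data))
    if integer:
        mat = mat.astype(np.int64)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "genes": out_dir / "genes.tsv",
        "barcodes": out_dir / "barcodes.tsv",
        "metadata": out_dir / "metadata.tsv",
    }
    spio.mmwrite(paths["matrix"], mat, field="integer" if integer else "real")
    pd.Series(adata.var_names).to_csv(paths["genes"], sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(paths["barcodes"], sep="\t", header=False, index=False)
    adata.obs.rename_axis("cell_id").reset_index().to_csv(paths["metadata"], sep="\t", index=False)
    return paths


def load_lr_table(path) -> pd.DataFrame:
    """Two-column ligand/receptor TSV (header optional)."""
    table = pd.read_csv(path, sep="\t")
    if list(table.columns[:2]) != ["ligand", "receptor"]:
        table = pd.read_csv(path, sep="\t", header=None, names=["ligand", "receptor"])
    if table.shape[1] < 2 or table.empty:
        raise ValueError("ligand-receptor table needs two non-empty columns")
    return table[["ligand", "receptor"]]
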