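"""Readers and writers for the pipeline's plain-text interchange formats.

Single-cell datasets travel as a directory of Matrix Market counts
(genes as rows, 1-based coordinate indices) plus ``genes.tsv`` (id, symbol)
and ``cells.tsv`` (barcode, donor); bulk pairs, gene sets (GMT), scores,
pseudotime and candidate tables as TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import io as spio
from scipy import sparse

from .bulk import BulkPair, GeneSet

__all__ = [
    "write_cell_dir",
    "read_cell_dir",
    "read_bulk_tsv",
    "write_bulk_tsv",
    "read_gmt",
    "write_gmt",
]


def write_cell_dir(adata: AnnData, out_dir: str | Path) -> Path:
    """Write counts + gene/cell tables (MTX layout, genes as rows)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X = adata.X
    mat = X.T if sparse.issparse(X) else sparse.csr_matrix(np.asarray(X).T)
    spio.mmwrite(out / "matrix.mtx", sparse.coo_matrix(mat), field="integer")
    genes = pd.DataFrame(
        {"gene_id": adata.var_names, "symbol": adata.var.get("symbol", adata.var_names)}
    )
    genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    cells = pd.DataFrame({"barcode": adata.obs_names, "donor": adata.obs["donor"]})
    cells.to_csv(out / "cells.tsv", sep="\t", index=False)
    return out


def read_cell_dir(in_dir: str | Path) -> AnnData:
    """Read a counts directory written by :func:`write_cell_dir`."""
    d = Path(in_dir)
    mat = spio.mmread(d / "matrix.mtx").tocsr()  # genes x cells
    genes = pd.read_csv(d / "genes.tsv", sep="\t", dtype=str)
    cells = pd.read_csv(d / "cells.tsv", sep="\t", dtype=str)
    if mat.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {mat.shape} inconsistent with genes.tsv ({len(genes)}) / cells.tsv ({len(cells)})"
        )
    var = genes.set_index("gene_id")
    obs = cells.set_index("barcode")
    if "donor" not in obs.columns:
        raise ValueError("cells.tsv must carry a 'donor' column")
    return AnnData(X=mat.T.tocsr(), obs=obs, var=var)


def read_bulk_tsv(path: str | Path, epsilon: float = 0.01) -> BulkPair:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "tpm_retained", "tpm_reduced"}
    if not required.issubset(df.columns):
        raise ValueError(f"bulk TSV must have columns {sorted(required)}")
    return BulkPair(table=df.set_index("gene_id"), epsilon=epsilon)


def write_bulk_tsv(pair_table: pd.DataFrame, path: str | Path) -> None:
    pair_table.reset_index().to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """GMT: one set per line — name, description, then member genes (tab-separated)."""
    sets: dict[str, GeneSet] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        name, members = fields[0], [g for g in fields[2:] if g]
        if not members:
            raise ValueError(f"gene set {name!r} has no members")
        sets[name] = GeneSet(name, frozenset(members))
    return sets


def write_gmt(sets: dict[str, GeneSet] | list[GeneSet], path: str | Path, description: str = "") -> None:
    if isinstance(sets, dict):
        sets = list(sets.values())
    lines = [
        "\t".join([s.name, description] + sorted(s.members)) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")
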