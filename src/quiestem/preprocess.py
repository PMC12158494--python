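"""Single-cell preprocessing: depth normalization, epithelial gating, PCA, batch removal.

Normalization follows the median-depth size-factor convention with a
log10(x + 1) transform. Epithelial cells are gated as double-positive for two
gate genes (EpCAM-like / CDH1-like) on the normalized layer with a strict
threshold (default 0.1). Donor batch effects are removed in the PCA embedding,
either by donor centering (deterministic; exact for pure translations) or by a
sequential mutual-nearest-neighbour shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

__all__ = ["Embedding", "normalize", "gate_double_positive", "run_pca", "remove_batch"]

NORM_LAYER = "norm"


@dataclass
class Embedding:
    """Cells x d coordinates with provenance."""

    coordinates: pd.DataFrame  # index cell_id, columns dim1..dimd
    method: str
    variance_ratio: np.ndarray | None = None
    components: np.ndarray | None = None  # d x genes loadings (PCA only)

    def __post_init__(self) -> None:
        if self.coordinates.shape[1] < 2:
            raise ValueError("embedding needs at least 2 dimensions")

    @property
    def values(self) -> np.ndarray:
        return self.coordinates.to_numpy()

    @property
    def cell_ids(self) -> pd.Index:
        return self.coordinates.index


def _dense_counts(adata: AnnData) -> np.ndarray:
    X = adata.X
    return np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)


def normalize(adata: AnnData) -> AnnData:
    """Attach a ``norm`` layer: log10(count / size_factor + 1).

    Size factor of a cell is its total count divided by the median total, so
    scaling every cell's depth by a constant leaves the layer unchanged.
    """
    X = _dense_counts(adata).astype(float)
    totals = X.sum(axis=1)
    if (totals == 0).any():
        bad = list(adata.obs_names[totals == 0])
        raise ValueError(f"cells with zero total counts: {bad}")
    size_factors = totals / np.median(totals)
    out = adata.copy()
    out.layers[NORM_LAYER] = np.log10(X / size_factors[:, None] + 1.0)
    out.obs["size_factor"] = size_factors
    return out


def gate_double_positive(
    adata: AnnData, gene_a: str, gene_b: str, threshold: float = 0.1
) -> AnnData:
    """Keep cells with normalized expression of both gate genes strictly above threshold."""
    if NORM_LAYER not in adata.layers:
        raise ValueError("normalized layer missing; call normalize() first")
    for g in (gene_a, gene_b):
        if g not in adata.var_names:
            raise KeyError(f"gate gene {g!r} not present in dataset")
    norm = np.asarray(adata.layers[NORM_LAYER])
    ia = adata.var_names.get_loc(gene_a)
    ib = adata.var_names.get_loc(gene_b)
    keep = (norm[:, ia] > threshold) & (norm[:, ib] > threshold)
    return adata[keep].copy()


def run_pca(
    adata: AnnData, n_components: int = 50, center: bool = True, seed: int = 0
) -> Embedding:
    """PCA of the normalized layer with a fixed sign convention.

    Each component's sign is chosen so its largest-magnitude gene loading is
    positive, making the embedding reproducible across BLAS backends.
    """
    if n_components <= 0:
        raise ValueError("n_components must be positive")
    if NORM_LAYER not in adata.layers:
        raise ValueError("normalized layer missing; call normalize() first")
    M = np.asarray(adata.layers[NORM_LAYER], dtype=float)
    max_rank = min(M.shape[0] - 1, M.shape[1]) if center else min(M.shape)
    n_components = min(n_components, max_rank)
    Mc = M - M.mean(axis=0) if center else M
    U, S, Vt = np.linalg.svd(Mc, full_matrices=False)
    comps = Vt[:n_components]
    coords = U[:, :n_components] * S[:n_components]
    flip = np.sign(comps[np.arange(n_components), np.abs(comps).argmax(axis=1)])
    flip[flip == 0] = 1.0
    coords = coords * flip[None, :]
    total_var = (S**2).sum()
    var_ratio = (S[:n_components] ** 2) / total_var if total_var > 0 else S[:n_components] * 0
    cols = [f"dim{i + 1}" for i in range(n_components)]
    return Embedding(
        coordinates=pd.DataFrame(coords, index=adata.obs_names, columns=cols),
        method="pca",
        variance_ratio=var_ratio,
        components=comps * flip[:, None],
    )


def remove_batch(
    emb: Embedding, donors: pd.Series, mode: str = "center", k: int = 20
) -> Embedding:
    """Remove per-donor shifts from an embedding.

    ``center`` subtracts each donor's centroid and restores the global
    centroid — exact for translation-only batch effects and the deterministic
    default. ``mnn`` merges donors sequentially (largest first), shifting each
    incoming donor by the mean difference vector over its mutual nearest
    neighbour pairs with the already-merged cells.
    """
    donors = donors.reindex(emb.cell_ids)
    if donors.isna().any():
        raise ValueError("donor labels missing for some embedded cells")
    X = emb.values.copy()
    labels = donors.to_numpy()
    unique = pd.unique(labels)
    if len(unique) == 1:
        return Embedding(emb.coordinates.copy(), emb.method + f"+{mode}", emb.variance_ratio)

    if mode == "center":
        global_centroid = X.mean(axis=0)
        for d in unique:
            m = labels == d
            X[m] += global_centroid - X[m].mean(axis=0)
    elif mode == "mnn":
        sizes = {d: int((labels == d).sum()) for d in unique}
        small = [d for d, s in sizes.items() if s < k]
        if small:
            raise ValueError(
                f"donors {small} have fewer than k={k} cells; use mode='center'"
            )
        order = sorted(unique, key=lambda d: (-sizes[d], str(d)))
        merged = labels == order[0]
        from sklearn.neighbors import NearestNeighbors

        for d in order[1:]:
            inc = labels == d
            A, B = X[merged], X[inc]
            nn_ab = NearestNeighbors(n_neighbors=k).fit(B).kneighbors(A, return_distance=False)
            nn_ba = NearestNeighbors(n_neighbors=k).fit(A).kneighbors(B, return_distance=False)
            pairs = []
            ba_sets = [set(row) for row in nn_ba]
            for i, row in enumerate(nn_ab):
                for j in row:
                    if i in ba_sets[j]:
                        pairs.append((i, j))
            if pairs:
                ai, bj = zip(*pairs)
                shift = (A[list(ai)] - B[list(bj)]).mean(axis=0)
                X[inc] += shift
            merged |= inc
    else:
        raise ValueError(f"unknown batch mode {mode!r}")
    coords = pd.DataFrame(X, index=emb.cell_ids, columns=emb.coordinates.columns)
    return Embedding(coords, emb.method + f"+{mode}", emb.variance_ratio)
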