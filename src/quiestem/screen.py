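"""Trajectory-gene screening and monotone-decrease marker nomination.

Stage one scores every gene for spatial autocorrelation over a symmetric kNN
graph of the batch-corrected embedding with Moran's I,

    I = (n / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2,

and keeps genes whose BH-adjusted one-sided p underflows to zero ("q = 0", the
regime reached by normal-approximation p-values for strong smooth signals).
Stage two intersects the surviving genes across two independent datasets.
Stage three fits each gene's normalized expression against pseudotime with a
natural cubic spline and keeps genes whose fitted derivative is strictly
negative at every point of an evaluation grid — the monotone-decrease filter.
Candidates passing in both datasets are ranked by their abundance (TPM) in the
retained (quiescent) bulk condition.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .bulk import BulkPair
from .preprocess import Embedding

__all__ = [
    "MoranResult",
    "SplineFit",
    "build_knn_graph",
    "morans_i",
    "morans_i_batch",
    "morans_test",
    "bh_adjust",
    "select_trajectory_genes",
    "intersect_datasets",
    "fit_spline",
    "monotone_decreasing",
    "rank_candidates",
]

logger = logging.getLogger(__name__)


@dataclass
class MoranResult:
    gene_id: str
    morans_i: float
    p_value: float
    q_value: float | None = None


def build_knn_graph(emb: Embedding, k: int = 15) -> sparse.csr_matrix:
    """Symmetric binary kNN adjacency (union of directed relations, no self-loops).

    Neighbour ties at equal distance break by cell index so the graph is
    reproducible.
    """
    X = emb.values
    n = X.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    if n <= 4000:
        from scipy.spatial.distance import squareform, pdist

        D = squareform(pdist(X))
        np.fill_diagonal(D, np.inf)
        idx = np.arange(n)
        rows, cols = [], []
        for i in range(n):
            order = np.lexsort((idx, D[i]))[:k]
            rows.extend([i] * k)
            cols.extend(order.tolist())
    else:
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
        neigh = nn.kneighbors(X, return_distance=False)
        rows, cols = [], []
        for i in range(n):
            js = [j for j in neigh[i] if j != i][:k]
            rows.extend([i] * len(js))
            cols.extend(js)
    A = sparse.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    A = ((A + A.T) > 0).astype(float)
    A.setdiag(0)
    A.eliminate_zeros()
    return A.tocsr()


def _as_adjacency(graph) -> sparse.csr_matrix:
    if sparse.issparse(graph):
        return graph.tocsr()
    import networkx as nx

    if isinstance(graph, nx.Graph):
        return nx.to_scipy_sparse_array(graph, weight="weight", format="csr")
    return sparse.csr_matrix(np.asarray(graph))


def morans_i(x: np.ndarray, graph) -> float:
    """Moran's I of values ``x`` over a weighted adjacency."""
    A = _as_adjacency(graph)
    x = np.asarray(x, dtype=float)
    n = x.size
    W = A.sum()
    if W == 0:
        raise ValueError("graph has no edges")
    z = x - x.mean()
    den = float(z @ z)
    if den == 0:
        raise ValueError("constant gene: Moran's I undefined")
    num = float(z @ (A @ z))
    return (n / W) * num / den


def morans_i_batch(X: np.ndarray, graph) -> np.ndarray:
    """Moran's I for every row of a genes x cells matrix (NaN for constant rows)."""
    A = _as_adjacency(graph)
    n = X.shape[1]
    W = A.sum()
    Z = X - X.mean(axis=1, keepdims=True)
    AZ = (A @ Z.T).T
    num = np.einsum("gc,gc->g", AZ, Z)
    den = np.einsum("gc,gc->g", Z, Z)
    out = np.full(X.shape[0], np.nan)
    ok = den > 0
    out[ok] = (n / W) * num[ok] / den[ok]
    return out


def _graph_stats(A: sparse.csr_matrix) -> tuple[float, float, float]:
    """Spatial-weight sums S0, S1, S2 used by the randomization variance."""
    S0 = float(A.sum())
    C = A + A.T
    S1 = 0.5 * float(C.multiply(C).sum())
    rs = np.asarray(A.sum(axis=1)).ravel()
    cs = np.asarray(A.sum(axis=0)).ravel()
    S2 = float(((rs + cs) ** 2).sum())
    return S0, S1, S2


def _randomization_moments(
    n: int, S0: float, S1: float, S2: float, z: np.ndarray
) -> tuple[float, float]:
    """E[I] and Var[I] under random relabeling of the observed values."""
    EI = -1.0 / (n - 1)
    m2 = (z**2).sum() / n
    m4 = (z**4).sum() / n
    b2 = m4 / m2**2
    num = n * ((n**2 - 3 * n + 3) * S1 - n * S2 + 3 * S0**2) - b2 * (
        (n**2 - n) * S1 - 2 * n * S2 + 6 * S0**2
    )
    var = num / ((n - 1) * (n - 2) * (n - 3) * S0**2) - EI**2
    return EI, max(var, 0.0)


def _moments(A: sparse.csr_matrix, z: np.ndarray) -> tuple[float, float]:
    S0, S1, S2 = _graph_stats(A)
    return _randomization_moments(z.size, S0, S1, S2, z)


def morans_test(
    x: np.ndarray,
    graph,
    mode: str = "normal",
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """One-sided (positive autocorrelation) p-value for Moran's I.

    ``normal`` uses the randomization-null normal approximation — the only
    mode whose p-values can underflow to exactly 0 for overwhelming signals.
    ``permutation`` relabels ``x`` over nodes with the add-one convention;
    ``exhaustive`` enumerates all n! relabelings (n <= 8) and returns the
    plain exceedance proportion.
    """
    A = _as_adjacency(graph)
    x = np.asarray(x, dtype=float)
    obs = morans_i(x, A)
    n = x.size
    if mode == "normal":
        z = x - x.mean()
        EI, var = _moments(A, z)
        if var == 0:
            return 1.0
        return float(stats.norm.sf((obs - EI) / math.sqrt(var)))
    if mode == "permutation":
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100 in permutation mode")
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            if morans_i(rng.permutation(x), A) >= obs - 1e-12:
                exceed += 1
        return (1 + exceed) / (1 + n_perm)
    if mode == "exhaustive":
        if n > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8")
        count = total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if morans_i(x[list(perm)], A) >= obs - 1e-12:
                count += 1
        return count / total
    raise ValueError(f"unknown mode {mode!r}")


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def moran_screen(
    X: np.ndarray,
    gene_ids,
    graph,
    mode: str = "normal",
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Moran's I + p + BH q for every row of a genes x cells expression matrix.

    Constant genes are reported with NaN I and p = 1 (they cannot vary along
    any trajectory).
    """
    A = _as_adjacency(graph)
    I = morans_i_batch(X, A)
    n = X.shape[1]
    p = np.ones(X.shape[0])
    if mode == "normal":
        S0, S1, S2 = _graph_stats(A)  # graph moments are gene-independent
        for g in range(X.shape[0]):
            if np.isnan(I[g]):
                continue
            z = X[g] - X[g].mean()
            EI, var = _randomization_moments(n, S0, S1, S2, z)
            p[g] = stats.norm.sf((I[g] - EI) / math.sqrt(var)) if var > 0 else 1.0
    else:
        for g in range(X.shape[0]):
            if np.isnan(I[g]):
                continue
            p[g] = morans_test(X[g], A, mode=mode, n_perm=n_perm, seed=seed + g)
    q = bh_adjust(p)
    return pd.DataFrame({"morans_i": I, "p_value": p, "q_value": q}, index=pd.Index(gene_ids, name="gene_id"))


def select_trajectory_genes(results: pd.DataFrame, q_zero_tol: float = 1e-300) -> list[str]:
    """Genes whose q-value is (numerically) zero: q <= ``q_zero_tol``.

    This operationalizes an underflow-level cutoff; sampled-permutation
    p-values are bounded below by 1/(1+n_perm) and can never satisfy it, in
    which case a warning suggests normal mode or a raised tolerance.
    """
    if results.empty:
        raise ValueError("empty Moran results")
    selected = sorted(results.index[results["q_value"] <= q_zero_tol])
    if not selected and (results["q_value"] > 0).all():
        warnings.warn(
            "no gene reaches q = 0; sampled permutation p-values cannot underflow — "
            "use mode='normal' or raise q_zero_tol",
            stacklevel=2,
        )
    return selected


def intersect_datasets(genes_1, genes_2) -> list[str]:
    """Sorted intersection of two trajectory-gene selections."""
    return sorted(set(genes_1) & set(genes_2))


@dataclass
class SplineFit:
    """Natural cubic spline fit of expression against pseudotime."""

    gene_id: str
    knots: np.ndarray  # boundary + interior knots, ascending
    coef: np.ndarray  # intercept + df basis coefficients
    df: int

    def _basis(self, t: np.ndarray, deriv: bool = False) -> np.ndarray:
        return _ns_basis(np.asarray(t, dtype=float), self.knots, deriv=deriv)

    def predict(self, t: np.ndarray) -> np.ndarray:
        B = self._basis(t)
        return self.coef[0] + B @ self.coef[1:]

    def derivative(self, t: np.ndarray) -> np.ndarray:
        B1 = self._basis(t, deriv=True)
        return B1 @ self.coef[1:]


def _ns_basis(t: np.ndarray, knots: np.ndarray, deriv: bool = False) -> np.ndarray:
    """Natural cubic spline basis (truncated-power construction, no intercept).

    With K knots (boundary included) the basis has K - 1 columns:
    N_1(x) = x and N_{k+1}(x) = d_k(x) - d_{K-1}(x), k = 1..K-2, where
    d_k(x) = [(x - xi_k)^3_+ - (x - xi_K)^3_+] / (xi_K - xi_k). The resulting
    space is C^2 with zero second derivative outside the boundary knots and
    contains all linear functions exactly.
    """
    K = knots.size
    xiK = knots[-1]

    def dk(k: int) -> np.ndarray:
        denom = xiK - knots[k]
        if deriv:
            return (3 * np.clip(t - knots[k], 0, None) ** 2 - 3 * np.clip(t - xiK, 0, None) ** 2) / denom
        return (np.clip(t - knots[k], 0, None) ** 3 - np.clip(t - xiK, 0, None) ** 3) / denom

    cols = [np.ones_like(t) if deriv else t]
    if K >= 3:
        dlast = dk(K - 2)
        for k in range(K - 2):
            cols.append(dk(k) - dlast)
    return np.column_stack(cols)


def fit_spline(t: np.ndarray, y: np.ndarray, df: int = 3, gene_id: str = "") -> SplineFit:
    """Least-squares natural cubic spline of ``y`` on pseudotime ``t``.

    ``df`` basis functions (plus intercept); interior knots at pseudotime
    quantiles, boundary knots at the observed range.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    distinct = np.unique(t)
    if distinct.size < df + 2:
        raise ValueError(f"need at least df + 2 = {df + 2} distinct pseudotimes, got {distinct.size}")
    n_interior = df - 1
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(t, qs) if n_interior > 0 else np.array([])
    knots = np.unique(np.concatenate([[t.min()], interior, [t.max()]]))
    B = _ns_basis(t, knots)
    Xmat = np.column_stack([np.ones_like(t), B])
    coef, *_ = np.linalg.lstsq(Xmat, y, rcond=None)
    return SplineFit(gene_id=gene_id, knots=knots, coef=coef, df=B.shape[1])


def monotone_decreasing(fit: SplineFit, grid: np.ndarray) -> bool:
    """True iff the fitted derivative is strictly negative at every grid point."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty evaluation grid")
    return bool((fit.derivative(grid) < 0).all())


def rank_candidates(genes, pair: BulkPair) -> pd.DataFrame:
    """Rank surviving candidates by retained-condition TPM (descending).

    Genes missing from the bulk pair carry NaN TPM and sort last. Rank 1 is
    the top marker nominee.
    """
    genes = list(genes)
    eps = pair.epsilon
    tab = pair.table.reindex(genes)
    missing = tab["tpm_retained"].isna()
    if missing.any():
        logger.warning("genes missing from bulk pair ranked last: %s", list(tab.index[missing]))
    tab = tab.assign(
        ratio=(tab["tpm_retained"] + eps) / (tab["tpm_reduced"] + eps)
    )
    tab = tab.sort_values("tpm_retained", ascending=False, na_position="last", kind="mergesort")
    tab["rank"] = np.arange(1, len(tab) + 1)
    tab.index.name = "gene_id"
    return tab
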