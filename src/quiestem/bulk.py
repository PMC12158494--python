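"""Bulk retained/reduced contrast: TPM, dormancy score, gene-set selection, GSEA.

The dormancy statistic combines fold-enrichment in the quiescent ("retained")
condition with absolute abundance there:

    score(g) = log10((r_g + eps) / (d_g + eps)) * log10(r_g + eps)

with r = TPM retained, d = TPM reduced and a pseudocount eps (default 0.01)
applied to every TPM before both factors so the statistic is defined at zero.
Genes with score strictly above a threshold (default 2) form the dormancy set.

GSEA on the ratio-preranked vector uses the classical weighted running-sum
enrichment score with a gene-permutation null: with only two bulk samples a
phenotype permutation is impossible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BulkPair",
    "GeneSet",
    "GseaResult",
    "compute_tpm",
    "dormancy_score",
    "dormancy_scores",
    "select_dormancy_set",
    "preranked_vector",
    "gsea_es",
    "gsea_permutation",
    "map_gene_ids",
]

logger = logging.getLogger(__name__)


@dataclass
class BulkPair:
    """Per-gene TPM of the retained (quiescent) and reduced (proliferative) pools."""

    table: pd.DataFrame  # index gene_id; columns tpm_retained, tpm_reduced
    epsilon: float = 0.01

    def __post_init__(self) -> None:
        required = {"tpm_retained", "tpm_reduced"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"bulk table must have columns {sorted(required)}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not self.table.index.is_unique:
            raise ValueError("gene ids must be unique")
        if (self.table[list(required)].to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index


@dataclass
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float  # NaN when too few same-sign permutations
    p_value: float
    ranked_hits: tuple[int, ...]  # 1-based positions of set members in the ranking


def compute_tpm(counts: np.ndarray, lengths_kb: np.ndarray) -> np.ndarray:
    """Transcripts per million from read counts and effective lengths (kb)."""
    counts = np.asarray(counts, dtype=float)
    lengths_kb = np.asarray(lengths_kb, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if (lengths_kb <= 0).any():
        raise ValueError("lengths must be positive")
    rate = counts / lengths_kb
    total = rate.sum()
    if total == 0:
        raise ValueError("all-zero counts: TPM undefined")
    return rate / total * 1e6


def dormancy_scores(pair: BulkPair) -> pd.Series:
    """Dormancy statistic for every gene in the pair."""
    eps = pair.epsilon
    r = pair.table["tpm_retained"].to_numpy() + eps
    d = pair.table["tpm_reduced"].to_numpy() + eps
    return pd.Series(np.log10(r / d) * np.log10(r), index=pair.gene_ids, name="dormancy_score")


def dormancy_score(pair: BulkPair, gene: str) -> float:
    if gene not in pair.gene_ids:
        raise KeyError(f"gene {gene!r} not in bulk pair")
    return float(dormancy_scores(pair).loc[gene])


def select_dormancy_set(pair: BulkPair, threshold: float = 2.0) -> GeneSet:
    """Genes whose dormancy score exceeds ``threshold`` (strict), as printed."""
    scores = dormancy_scores(pair)
    members = frozenset(scores.index[scores > threshold])
    if not members:
        warnings.warn("dormancy selection is empty at this threshold", stacklevel=2)
    return GeneSet("dormancy", members)


def preranked_vector(pair: BulkPair) -> list[tuple[str, float]]:
    """Genes ranked descending by pseudocounted retained/reduced TPM ratio.

    Ties are broken lexicographically by gene id so the ranking (and hence any
    downstream enrichment score) is reproducible.
    """
    eps = pair.epsilon
    ratio = (pair.table["tpm_retained"] + eps) / (pair.table["tpm_reduced"] + eps)
    order = sorted(ratio.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(g, float(s)) for g, s in order]


def _running_sum(scores: np.ndarray, hit_mask: np.ndarray, weight_p: float) -> np.ndarray:
    n = scores.size
    n_hits = int(hit_mask.sum())
    w = np.abs(scores[hit_mask]) ** weight_p
    denom = w.sum()
    steps = np.where(hit_mask, 0.0, -1.0 / (n - n_hits))
    if denom == 0:
        # degenerate all-zero hit scores: equal hit mass
        steps[hit_mask] = 1.0 / n_hits
    else:
        steps[hit_mask] = (np.abs(scores[hit_mask]) ** weight_p) / denom
    return np.cumsum(steps)


def gsea_es(ranked: list[tuple[str, float]], gene_set: GeneSet, weight_p: float = 1.0) -> float:
    """Weighted Kolmogorov–Smirnov-like enrichment score on a preranked vector.

    The running sum gains |s_i|^p (normalized over hits) at set members and
    loses 1/(N - |S|) elsewhere; the ES is the signed extremum.
    """
    genes = np.array([g for g, _ in ranked])
    scores = np.array([s for _, s in ranked], dtype=float)
    hit_mask = np.isin(genes, list(gene_set.members))
    if not hit_mask.any():
        raise ValueError("gene set is disjoint from the ranked universe")
    if hit_mask.all():
        raise ValueError("gene set equals the ranked universe")
    rs = _running_sum(scores, hit_mask, weight_p)
    return float(rs[np.argmax(np.abs(rs))])


def gsea_permutation(
    ranked: list[tuple[str, float]],
    gene_set: GeneSet,
    n_perm: int = 10_000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> GseaResult:
    """Gene-permutation GSEA p-value and NES for one set.

    p uses the add-one convention on the same-sign tail; NES divides the
    observed ES by the mean |permutation ES| of the same sign (NaN when fewer
    than 10 same-sign permutations exist).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    genes = np.array([g for g, _ in ranked])
    scores = np.array([s for _, s in ranked], dtype=float)
    hit_mask = np.isin(genes, list(gene_set.members))
    es = gsea_es(ranked, gene_set, weight_p)
    n, n_hits = genes.size, int(hit_mask.sum())

    rng = np.random.default_rng(seed)
    perm_es = np.empty(n_perm)
    for i in range(n_perm):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=n_hits, replace=False)] = True
        rs = _running_sum(scores, mask, weight_p)
        perm_es[i] = rs[np.argmax(np.abs(rs))]

    if es >= 0:
        exceed = int((perm_es >= es).sum())
        same_sign = perm_es[perm_es >= 0]
    else:
        exceed = int((perm_es <= es).sum())
        same_sign = -perm_es[perm_es < 0]
    p = (1 + exceed) / (1 + n_perm)
    nes = es / same_sign.mean() if same_sign.size >= 10 else float("nan")
    hits = tuple(int(i) + 1 for i in np.flatnonzero(hit_mask))
    return GseaResult(gene_set.name, es, float(nes), float(p), hits)


def map_gene_ids(mapping: pd.DataFrame, expression: pd.Series) -> pd.DataFrame:
    """Resolve symbol <-> Ensembl multiplicity to a one-to-one table.

    ``mapping`` needs columns ``symbol`` and ``ensembl_id`` (optionally
    ``priority`` marking the preferred symbol when an id maps to several).
    For a symbol carried by several ids, the id with the highest total
    expression wins; ids without a symbol are dropped and logged.
    """
    df = mapping.copy()
    df["expression"] = df["ensembl_id"].map(expression)
    blank = df["symbol"].isna() | (df["symbol"].astype(str).str.len() == 0)
    if blank.any():
        logger.info("dropping %d ids with no symbol", int(blank.sum()))
        df = df[~blank]
    df = df[df["expression"].notna()]
    # an id mapping to several symbols: keep the priority row if given, else first
    if "priority" in df.columns:
        df = df.sort_values(["ensembl_id", "priority"], ascending=[True, False])
    df = df.drop_duplicates("ensembl_id", keep="first")
    # a symbol with several ids: keep the most expressed id
    df = df.sort_values(["symbol", "expression"], ascending=[True, False])
    df = df.drop_duplicates("symbol", keep="first")
    return df.reset_index(drop=True)[["symbol", "ensembl_id", "expression"]]
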