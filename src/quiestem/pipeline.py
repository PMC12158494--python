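"""End-to-end orchestration of the two-dataset marker discovery analysis.

Order of operations: bulk contrast -> dormancy gene set; then per single-cell
dataset: normalize -> epithelial gate -> PCA -> donor batch removal ->
dormancy AUC scoring -> principal tree -> root at the top-scoring cell ->
geodesic pseudotime -> Moran's I screen (q = 0); then the cross-dataset
intersection, the per-dataset natural-spline monotone-decrease filter, and
ranking of survivors by retained-condition TPM.

Every stage writes its table under the output directory and is reused on
re-runs when its file already exists and the configuration is unchanged, so
the pipeline is resumable and, in the deterministic modes (batch "center",
Moran "normal"), bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as qio
from . import preprocess, scoring, screen, trajectory
from .bulk import BulkPair, GeneSet, dormancy_scores, select_dormancy_set

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.17g"  # round-trips doubles exactly through TSV


@dataclass
class PipelineConfig:
    """Paths and stage parameters for one full run."""

    bulk_path: str
    dataset_paths: list[str]  # two single-cell count directories
    gate_gene_a: str
    gate_gene_b: str
    gene_sets_path: str | None = None  # optional GMT for bulk GSEA
    weights_path: str | None = None  # optional footprint weight TSV
    epsilon: float = 0.01
    dormancy_threshold: float = 2.0
    gate_threshold: float = 0.1
    max_rank_fraction: float = 0.05
    n_pcs: int = 50
    batch_mode: str = "center"
    mnn_k: int = 20
    n_nodes: int | None = None
    knn_k: int = 15
    moran_mode: str = "normal"
    n_perm: int = 999
    q_zero_tol: float = 1e-300
    spline_df: int = 3
    grid_size: int = 100
    make_plots: bool = False
    seed: int = 7

    def validate(self) -> None:
        if len(self.dataset_paths) != 2:
            raise ValueError("exactly two single-cell dataset paths are required")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not (0 < self.max_rank_fraction <= 1):
            raise ValueError("max_rank_fraction must be in (0, 1]")
        if self.n_pcs <= 0:
            raise ValueError("n_pcs must be positive")
        if self.batch_mode not in ("center", "mnn"):
            raise ValueError("batch_mode must be 'center' or 'mnn'")
        if self.moran_mode not in ("normal", "permutation"):
            raise ValueError("moran_mode must be 'normal' or 'permutation'")
        if self.knn_k <= 0:
            raise ValueError("knn_k must be positive")
        if self.spline_df < 1:
            raise ValueError("spline_df must be >= 1")
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if self.q_zero_tol < 0:
            raise ValueError("q_zero_tol must be >= 0")


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse, default and range-check a YAML pipeline configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}; valid keys: {sorted(valid)}")
    missing = {"bulk_path", "dataset_paths", "gate_gene_a", "gate_gene_b"} - set(raw)
    if missing:
        raise ValueError(f"missing mandatory config keys: {sorted(missing)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    for p in [cfg.bulk_path, *cfg.dataset_paths]:
        if not Path(p).exists():
            raise FileNotFoundError(f"configured input path does not exist: {p}")
    return cfg


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def _cached_tsv(path: Path, compute, index_col=0) -> pd.DataFrame:
    """Load a stage table if already on disk, else compute and persist it."""
    if path.exists():
        logger.info("reusing cached %s", path.name)
        return pd.read_csv(path, sep="\t", index_col=index_col)
    df = compute()
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)
    return df


def _analyze_dataset(
    ds_dir: str, out: Path, config: PipelineConfig, dormancy: GeneSet, report: dict
) -> dict:
    """One dataset's path from counts to Moran q-values and pseudotime."""
    tag = out.name
    out.mkdir(parents=True, exist_ok=True)
    adata = qio.read_cell_dir(ds_dir)
    report["n_cells_total"] = int(adata.n_obs)
    report["n_genes"] = int(adata.n_vars)

    adata = preprocess.normalize(adata)
    gated = preprocess.gate_double_positive(
        adata, config.gate_gene_a, config.gate_gene_b, config.gate_threshold
    )
    report["n_cells_gated"] = int(gated.n_obs)
    if gated.n_obs == 0:
        raise ValueError(f"[{tag}] no double-positive cells after gating")

    emb_path = out / "embedding.tsv"
    if emb_path.exists():
        coords = pd.read_csv(emb_path, sep="\t", index_col=0)
        emb = preprocess.Embedding(coords, "pca+cached")
    else:
        emb = preprocess.run_pca(gated, n_components=config.n_pcs, seed=config.seed)
        emb = preprocess.remove_batch(emb, gated.obs["donor"], mode=config.batch_mode, k=config.mnn_k)
        emb.coordinates.to_csv(emb_path, sep="\t", float_format=FLOAT_FMT)

    scores_path = out / "dormancy_auc.tsv"
    if scores_path.exists():
        sc = pd.read_csv(scores_path, sep="\t", index_col=0)["dormancy"]
        enr = scoring.EnrichmentScores(sc, "dormancy", 0)
    else:
        enr = scoring.auc_score(gated, dormancy, config.max_rank_fraction)
        enr.scores.to_frame("dormancy").to_csv(scores_path, sep="\t", float_format=FLOAT_FMT)

    pt_path = out / "pseudotime.tsv"
    if pt_path.exists():
        pt = pd.read_csv(pt_path, sep="\t", index_col=0)["pseudotime"]
    else:
        graph = trajectory.learn_graph(emb, n_nodes=config.n_nodes, seed=config.seed)
        graph = trajectory.select_root(graph, emb, enr)
        assign = trajectory.assign_pseudotime(graph, emb)
        pt = assign.pseudotime
        pt.to_frame().to_csv(pt_path, sep="\t", float_format=FLOAT_FMT)
        edges = pd.DataFrame(
            [
                {"u": u, "v": v, "length": w}
                for u, v, w in graph.graph.edges(data="weight")
            ]
        )
        edges["root"] = graph.root
        edges.to_csv(out / "graph_edges.tsv", sep="\t", index=False, float_format=FLOAT_FMT)

    moran_path = out / "moran.tsv"
    norm = np.asarray(gated.layers[preprocess.NORM_LAYER]).T  # genes x cells

    def _moran() -> pd.DataFrame:
        knn = screen.build_knn_graph(emb, k=config.knn_k)
        return screen.moran_screen(
            norm, gated.var_names, knn, mode=config.moran_mode,
            n_perm=config.n_perm, seed=config.seed,
        )

    moran = _cached_tsv(moran_path, _moran)
    selected = screen.select_trajectory_genes(moran, config.q_zero_tol)
    report["n_moran_q0"] = len(selected)
    return {
        "gated": gated,
        "pseudotime": pt,
        "moran": moran,
        "selected": selected,
        "norm": norm,
    }


def _monotone_flags(
    state: dict, genes: list[str], config: PipelineConfig, out: Path
) -> pd.Series:
    path = out / "monotone.tsv"
    if path.exists():
        df = pd.read_csv(path, sep="\t", index_col=0)
        return df["monotone_dec"].astype(bool)
    gated = state["gated"]
    pt = state["pseudotime"].reindex(gated.obs_names).to_numpy()
    grid = np.linspace(pt.min(), pt.max(), config.grid_size)
    flags = {}
    for g in genes:
        y = state["norm"][gated.var_names.get_loc(g)]
        fit = screen.fit_spline(pt, y, df=config.spline_df, gene_id=g)
        flags[g] = screen.monotone_decreasing(fit, grid)
    s = pd.Series(flags, name="monotone_dec")
    s.index.name = "gene_id"
    s.to_frame().to_csv(path, sep="\t")
    return s


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> tuple[pd.DataFrame, dict]:
    """Run the full two-dataset analysis; returns (candidate table, run report)."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    logging.getLogger("quiestem").addHandler(log_handler)

    # invalidate the cache when the configuration changed
    hash_path = out / "config_hash.txt"
    h = _config_hash(config)
    if hash_path.exists() and hash_path.read_text().strip() != h:
        logger.warning("configuration changed; clearing cached stage outputs in %s", out)
        for p in out.rglob("*.tsv"):
            p.unlink()
    hash_path.write_text(h + "\n")
    (out / "config_echo.yaml").write_text(yaml.safe_dump(dataclasses.asdict(config)))

    report: dict = {"parameters": dataclasses.asdict(config), "stages": {}, "timings_s": {}}
    t0 = time.perf_counter()

    pair = qio.read_bulk_tsv(config.bulk_path, epsilon=config.epsilon)
    scores = dormancy_scores(pair)
    scores.to_frame().to_csv(out / "dormancy_scores.tsv", sep="\t", float_format=FLOAT_FMT)
    dormancy = select_dormancy_set(pair, config.dormancy_threshold)
    if not dormancy.members:
        raise ValueError("empty dormancy gene set; lower dormancy_threshold")
    qio.write_gmt([dormancy], out / "dormancy_set.gmt")
    report["stages"]["bulk"] = {"n_genes_bulk": int(len(pair.gene_ids)),
                                "n_dormancy_genes": len(dormancy.members)}
    report["timings_s"]["bulk"] = round(time.perf_counter() - t0, 3)

    states = []
    for i, ds in enumerate(config.dataset_paths, start=1):
        t1 = time.perf_counter()
        ds_report: dict = {}
        state = _analyze_dataset(ds, out / f"ds{i}", config, dormancy, ds_report)
        report["stages"][f"ds{i}"] = ds_report
        report["timings_s"][f"ds{i}"] = round(time.perf_counter() - t1, 3)
        states.append(state)

    t2 = time.perf_counter()
    intersection = screen.intersect_datasets(states[0]["selected"], states[1]["selected"])
    report["stages"]["intersection"] = {"n_genes": len(intersection)}

    flags = [
        _monotone_flags(state, intersection, config, out / f"ds{i}")
        for i, state in enumerate(states, start=1)
    ]
    passing = [g for g in intersection if flags[0].get(g, False) and flags[1].get(g, False)]
    report["stages"]["monotone"] = {
        "n_monotone_ds1": int(flags[0].sum()) if len(flags[0]) else 0,
        "n_monotone_ds2": int(flags[1].sum()) if len(flags[1]) else 0,
        "n_candidates": len(passing),
    }

    candidates = screen.rank_candidates(passing, pair)
    candidates.to_csv(out / "candidates.tsv", sep="\t", float_format=FLOAT_FMT)
    report["timings_s"]["screen"] = round(time.perf_counter() - t2, 3)
    report["timings_s"]["total"] = round(time.perf_counter() - t0, 3)

    if config.make_plots:
        _report_plots(states, candidates, config, out)

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    logging.getLogger("quiestem").removeHandler(log_handler)
    log_handler.close()
    return candidates, report


def _report_plots(states, candidates: pd.DataFrame, config: PipelineConfig, out: Path) -> None:
    """Embedding/pseudotime scatter and a spline curve for the top candidate."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for i, (ax, state) in enumerate(zip(axes, states), start=1):
        emb = pd.read_csv(out / f"ds{i}" / "embedding.tsv", sep="\t", index_col=0)
        sc = ax.scatter(emb.iloc[:, 0], emb.iloc[:, 1], c=state["pseudotime"], s=4, cmap="viridis")
        ax.set_title(f"dataset {i}: pseudotime")
        fig.colorbar(sc, ax=ax)
    fig.tight_layout()
    fig.savefig(out / "pseudotime_scatter.png", dpi=100)
    plt.close(fig)

    if len(candidates) > 0:
        top = candidates.index[0]
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        for i, (ax, state) in enumerate(zip(axes, states), start=1):
            gated = state["gated"]
            pt = state["pseudotime"].reindex(gated.obs_names).to_numpy()
            y = state["norm"][gated.var_names.get_loc(top)]
            fit = screen.fit_spline(pt, y, df=config.spline_df, gene_id=top)
            grid = np.linspace(pt.min(), pt.max(), 200)
            ax.scatter(pt, y, s=3, alpha=0.3)
            ax.plot(grid, fit.predict(grid), color="black")
            ax.set_title(f"dataset {i}: {top}")
            ax.set_xlabel("pseudotime")
        fig.tight_layout()
        fig.savefig(out / "top_candidate_spline.png", dpi=100)
        plt.close(fig)
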