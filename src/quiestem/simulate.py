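"""Synthetic two-study single-cell generator with a planted differentiation trajectory.

Emulates an epithelium in which a quiescent (dormant) population sits at the
root of a branching differentiation trajectory: root -> secretory early/mid/late,
with a ciliated branch splitting off mid-way. Expression programs are planted on
a per-cell latent time t in [0, 1]:

* dormancy program: maximal at the root; a designated subset decreases
  monotonically in t (these are the recoverable markers, including one
  "LCN2-like" gene guaranteed the highest baseline abundance),
* dormancy-only genes: drop early then rebound late (high at the root but
  deliberately non-monotone),
* peak genes: concave bump centered mid-trajectory (OVGP1-like),
* late genes: ramp up past a threshold time on the ciliated branch
  (FOXJ1/CAPS-like),
* two gate genes (EpCAM-like / CDH1-like): high only in epithelial cells.

Counts are negative binomial on a per-cell library size with per-donor
log-mean batch shifts. A matched bulk pair pools cells at the root
(latent time <= retained_time_max, the "retained" quiescent condition)
against the remainder (the "reduced" proliferative condition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cells",
    "simulate_bulk_pair",
    "DEFAULT_LAYOUT",
]

#: ordered (population label, latent time) pairs; the root sits at time 0 and
#: the ciliated branch terminal at time 1
DEFAULT_LAYOUT: tuple[tuple[str, float], ...] = (
    ("quiescent", 0.0),
    ("secretory_early", 0.25),
    ("secretory_mid", 0.5),
    ("secretory_late", 0.75),
    ("ciliated", 1.0),
)


@dataclass
class SimulationConfig:
    """Study conditions for the two-study synthetic benchmark.

    Counts of planted gene categories are disjoint except that the
    monotone-decreasing genes are a subset of the dormancy program.
    """

    n_genes: int = 1000
    n_cells_per_study: int = 2000
    n_donors: int = 3
    trajectory_layout: tuple[tuple[str, float], ...] = DEFAULT_LAYOUT
    n_dormancy_genes: int = 47
    n_monotone_decreasing_genes: int = 30
    n_peak_genes: int = 20
    n_late_genes: int = 20
    nb_dispersion: float = 5.0  # NB size; math.inf selects the Poisson limit
    batch_shift_sd: float = 0.3  # per-donor, per-gene shift on natural-log mean
    library_size_mean: float = 5000.0
    epithelial_fraction: float = 0.85
    retained_time_max: float = 0.1  # bulk "retained" pool: latent time <= this
    decreasing_slope: float = 4.0  # nat-log decrease of marker genes over t in [0,1]
    peak_amplitude: float = 2.0
    late_amplitude: float = 2.5
    branch_time: float = 0.5  # cells past this time commit to one of two branches
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_cells_per_study": self.n_cells_per_study,
            "n_dormancy_genes": self.n_dormancy_genes,
            "n_monotone_decreasing_genes": self.n_monotone_decreasing_genes,
            "n_peak_genes": self.n_peak_genes,
            "n_late_genes": self.n_late_genes,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.n_donors < 1:
            raise ValueError("n_donors must be >= 1")
        if self.n_cells_per_study < self.n_donors:
            raise ValueError(
                f"n_cells_per_study ({self.n_cells_per_study}) < n_donors ({self.n_donors})"
            )
        if len(self.trajectory_layout) == 0:
            raise ValueError("trajectory_layout must not be empty")
        times = [t for _, t in self.trajectory_layout]
        if any(t < 0 or t > 1 for t in times):
            raise ValueError("trajectory latent times must lie in [0, 1]")
        if sum(t == 0.0 for t in times) != 1:
            raise ValueError("exactly one population must sit at latent time 0")
        if self.n_monotone_decreasing_genes > self.n_dormancy_genes:
            raise ValueError("monotone-decreasing genes must be a subset of the dormancy program")
        # 2 gate genes are always appended to the marker block
        n_marker = self.n_dormancy_genes + self.n_peak_genes + self.n_late_genes + 2
        if n_marker > self.n_genes:
            raise ValueError("marker gene categories exceed n_genes")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive (math.inf for Poisson)")
        if self.batch_shift_sd < 0:
            raise ValueError("batch_shift_sd must be >= 0")
        if not (0 < self.epithelial_fraction <= 1):
            raise ValueError("epithelial_fraction must be in (0, 1]")


@dataclass
class GroundTruth:
    """Planted structure of one simulated study."""

    latent_time: pd.Series  # per cell, NaN for non-epithelial cells
    population: pd.Series  # per cell
    branch: pd.Series  # per cell: root / secretory / ciliated / none
    gene_category: pd.Series  # per gene: dormancy/decreasing/peak/late/gate/null
    batch_shift: pd.DataFrame  # donors x genes, natural-log shifts
    lcn2_like: str  # gene id of the designated top marker

    @property
    def decreasing_genes(self) -> list[str]:
        return list(self.gene_category.index[self.gene_category == "decreasing"])

    @property
    def dormancy_genes(self) -> list[str]:
        mask = self.gene_category.isin(["decreasing", "dormancy"])
        return list(self.gene_category.index[mask])


def _gene_table(config: SimulationConfig, rng: np.random.Generator):
    """Assign ids, symbols, categories and baseline natural-log abundances."""
    n = config.n_genes
    ids = np.array([f"SIMG{i:05d}" for i in range(n)])
    category = np.full(n, "null", dtype=object)
    n_dec = config.n_monotone_decreasing_genes
    n_dorm = config.n_dormancy_genes
    category[:n_dec] = "decreasing"
    category[n_dec:n_dorm] = "dormancy"  # dormancy program outside the monotone subset
    j = n_dorm
    category[j : j + config.n_peak_genes] = "peak"
    j += config.n_peak_genes
    category[j : j + config.n_late_genes] = "late"
    j += config.n_late_genes
    category[j : j + 2] = "gate"
    gate_ids = ids[j : j + 2]

    baseline = rng.normal(0.0, 0.8, size=n)
    # decreasing markers start high enough that a decreasing_slope-fold program
    # stays above the count floor over the whole trajectory (observable
    # monotonicity, not just monotonicity of the latent mean)
    baseline[category == "decreasing"] += 2.5
    baseline[category == "dormancy"] += 1.5
    baseline[(category == "peak") | (category == "late")] += 0.5
    lcn2_like = None
    if n_dec > 0:
        # the designated marker leads the retained-condition TPM ranking by construction
        dec_idx = np.flatnonzero(category == "decreasing")
        baseline[dec_idx[0]] = baseline[dec_idx].max() + 1.0
        lcn2_like = ids[dec_idx[0]]
    baseline[category == "gate"] = 1.5

    symbols = np.array(
        [f"{cat.upper()[:4]}-{gid[4:]}" for cat, gid in zip(category, ids)]
    )
    symbols[category == "gate"] = ["EPCAM-LIKE", "CDH1-LIKE"]
    return ids, symbols, category, baseline, gate_ids, lcn2_like


def _program_offsets(
    config: SimulationConfig,
    category: np.ndarray,
    t: np.ndarray,
    on_ciliated: np.ndarray,
) -> np.ndarray:
    """Natural-log offsets (genes x cells) added to baseline for epithelial cells."""
    n_genes, n_cells = category.size, t.size
    off = np.zeros((n_genes, n_cells))
    dec = category == "decreasing"
    off[dec, :] = -config.decreasing_slope * t[None, :]
    dorm = category == "dormancy"
    # early drop, late rebound: high at the root but non-monotone overall
    drop = np.clip((t - 0.05) / 0.35, 0.0, 1.0)
    rebound = np.clip((t - 0.65) / 0.35, 0.0, 1.0)
    off[dorm, :] = -3.0 * drop[None, :] + 2.0 * rebound[None, :]
    peak = category == "peak"
    off[peak, :] = config.peak_amplitude * np.exp(-((t - 0.5) ** 2) / (2 * 0.15**2))[None, :]
    late = category == "late"
    ramp = np.clip((t - 0.6) / 0.4, 0.0, 1.0) * on_ciliated
    off[late, :] = config.late_amplitude * ramp[None, :]
    return off


def simulate_cells(config: SimulationConfig) -> tuple[AnnData, GroundTruth]:
    """Draw one study's counts matrix and its ground truth.

    Returns an :class:`anndata.AnnData` with cells as observations, raw counts
    in ``X``, donor labels in ``obs['donor']``, and gene metadata in ``var``.
    Deterministic for a fixed config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    n_cells = config.n_cells_per_study
    ids, symbols, category, baseline, gate_ids, lcn2_like = _gene_table(config, rng)

    cell_ids = np.array([f"CELL{i:05d}" for i in range(n_cells)])
    donors = np.array([f"donor{(i % config.n_donors) + 1}" for i in range(n_cells)])
    epithelial = rng.random(n_cells) < config.epithelial_fraction
    t = rng.random(n_cells)
    t[~epithelial] = np.nan

    # population = nearest layout label below/around t; branch split past branch_time
    layout = sorted(config.trajectory_layout, key=lambda lt: lt[1])
    times = np.array([lt[1] for lt in layout])
    labels = np.array([lt[0] for lt in layout], dtype=object)
    pop = np.full(n_cells, "non_epithelial", dtype=object)
    ok = epithelial
    nearest = np.abs(t[ok, None] - times[None, :]).argmin(axis=1)
    pop[ok] = labels[nearest]

    branch = np.full(n_cells, "none", dtype=object)
    branch[ok] = "root"
    past = ok & (t > config.branch_time)
    choose_cil = rng.random(n_cells) < 0.5
    branch[past & choose_cil] = "ciliated"
    branch[past & ~choose_cil] = "secretory"
    # keep population labels consistent with the branch a cell committed to
    pop[(branch == "secretory") & (pop == "ciliated")] = "secretory_late"

    # natural-log relative abundance per gene per cell
    logmu = np.tile(baseline[:, None], (1, n_cells)).astype(float)
    t_fill = np.where(np.isnan(t), 0.0, t)
    offsets = _program_offsets(config, category, t_fill, (branch == "ciliated").astype(float))
    # non-epithelial cells do not run the epithelial trajectory programs:
    # program genes sit well below their epithelial baseline there
    program = np.isin(category, ["decreasing", "dormancy", "peak", "late"])
    offsets[:, ~epithelial] = 0.0
    offsets[np.ix_(program, ~epithelial)] = -2.0
    logmu += offsets
    # gate genes: high in epithelial cells, near-silent elsewhere
    gate_rows = np.isin(ids, gate_ids)
    logmu[np.ix_(gate_rows, ~epithelial)] = -5.0

    donor_names = [f"donor{i + 1}" for i in range(config.n_donors)]
    shifts = rng.normal(0.0, config.batch_shift_sd, size=(config.n_donors, config.n_genes))
    shift_df = pd.DataFrame(shifts, index=donor_names, columns=ids)
    donor_idx = np.array([donor_names.index(d) for d in donors])
    logmu += shifts[donor_idx, :].T

    # convert relative abundances to per-cell NB means on a drawn library size
    rel = np.exp(logmu)
    rel /= rel.sum(axis=0, keepdims=True)
    lib = rng.lognormal(math.log(config.library_size_mean) - 0.3**2 / 2, 0.3, size=n_cells)
    mean = rel * lib[None, :]

    if math.isinf(config.nb_dispersion):
        counts = rng.poisson(mean)
    else:
        size = config.nb_dispersion
        p = size / (size + mean)
        counts = rng.negative_binomial(size, p)

    from scipy import sparse

    adata = AnnData(
        X=sparse.csr_matrix(counts.T),
        obs=pd.DataFrame({"donor": donors}, index=cell_ids),
        var=pd.DataFrame({"symbol": symbols, "category": category}, index=ids),
    )
    truth = GroundTruth(
        latent_time=pd.Series(t, index=cell_ids, name="latent_time"),
        population=pd.Series(pop, index=cell_ids, name="population"),
        branch=pd.Series(branch, index=cell_ids, name="branch"),
        gene_category=pd.Series(category, index=ids, name="category"),
        batch_shift=shift_df,
        lcn2_like=lcn2_like,
    )
    return adata, truth


def simulate_bulk_pair(config: SimulationConfig, adata: AnnData, truth: GroundTruth) -> pd.DataFrame:
    """Pool simulated cells into a matched retained/reduced bulk TPM pair.

    "Retained" (quiescent) pools cells at latent time <= ``retained_time_max``;
    "reduced" (proliferative) pools the remainder, non-epithelial cells
    included. Simulated genes share a unit effective length, so TPM reduces to
    counts per million. Both columns sum to 1e6.
    """
    t = truth.latent_time.to_numpy()
    retained_mask = t <= config.retained_time_max  # NaN compares False
    reduced_mask = ~retained_mask
    if retained_mask.sum() == 0 or reduced_mask.sum() == 0:
        raise ValueError("one of the bulk pools is empty; adjust retained_time_max")
    X = np.asarray(adata.X.todense()) if hasattr(adata.X, "todense") else np.asarray(adata.X)
    pooled_ret = X[retained_mask, :].sum(axis=0).astype(float)
    pooled_red = X[reduced_mask, :].sum(axis=0).astype(float)

    def _tpm(v: np.ndarray) -> np.ndarray:
        total = v.sum()
        if total == 0:
            raise ValueError("bulk pool has zero total counts")
        return v / total * 1e6

    return pd.DataFrame(
        {"tpm_retained": _tpm(pooled_ret), "tpm_reduced": _tpm(pooled_red)},
        index=pd.Index(adata.var_names, name="gene_id"),
    )
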