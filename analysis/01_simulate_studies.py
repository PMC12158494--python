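"""Generate the two synthetic single-cell studies and the matched bulk pair.

Writes scratch/data/study1, scratch/data/study2 (MTX + gene/cell tables +
ground truth; raw matrices are large, so they live under scratch/) and
scratch/data/bulk_pair.tsv. The two studies share planted
gene categories but draw independent donor cohorts, baselines and noise; the
bulk pair pools study 1's root cells (latent time <= 0.1, the quiescent
"retained" condition) against everything else.
"""

import dataclasses
import sys
from pathlib import Path

import pandas as pd

from quiestem import io as qio
from quiestem.simulate import SimulationConfig, simulate_bulk_pair, simulate_cells

OUT = Path("scratch/data")
BASE_SEED = 1


def main() -> None:
    base = SimulationConfig()
    for i, seed in enumerate([2 * BASE_SEED, 2 * BASE_SEED + 1], start=1):
        cfg = dataclasses.replace(base, seed=seed)
        adata, truth = simulate_cells(cfg)
        out = OUT / f"study{i}"
        qio.write_cell_dir(adata, out)
        truth_df = pd.DataFrame(
            {
                "latent_time": truth.latent_time,
                "population": truth.population,
                "branch": truth.branch,
            }
        )
        truth_df.index.name = "barcode"
        truth_df.to_csv(out / "truth.tsv", sep="\t")
        truth.gene_category.to_frame().to_csv(out / "gene_truth.tsv", sep="\t")
        n_epi = int(truth.latent_time.notna().sum())
        print(
            f"study{i}: {adata.n_obs} cells ({n_epi} epithelial) x {adata.n_vars} genes, "
            f"designated marker {truth.lcn2_like}"
        )
        if i == 1:
            bulk = simulate_bulk_pair(cfg, adata, truth)
            qio.write_bulk_tsv(bulk, OUT / "bulk_pair.tsv")
            n_ret = int((truth.latent_time <= cfg.retained_time_max).sum())
            print(f"bulk pair: {n_ret} retained cells pooled vs {adata.n_obs - n_ret} reduced")


if __name__ == "__main__":
    sys.exit(main())
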