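"""Derive the dormancy gene set from the bulk retained/reduced contrast.

Scores every gene with log10((r+eps)/(d+eps)) * log10(r+eps), selects the
dormancy set at the score > 2 rule, and runs preranked GSEA of the planted
gene-category sets against the ratio-ranked vector as a sanity check: the
dormancy program should enrich at the top (positive ES), the late/ciliated
program at the bottom (negative ES).

Requires 01_simulate_studies.py. Writes results/bulk/.
"""

import sys
from pathlib import Path

import pandas as pd

from quiestem import io as qio
from quiestem.bulk import GeneSet, dormancy_scores, gsea_permutation, preranked_vector, select_dormancy_set

DATA = Path("scratch/data")
OUT = Path("results/bulk")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pair = qio.read_bulk_tsv(DATA / "bulk_pair.tsv")
    scores = dormancy_scores(pair)
    scores.sort_values(ascending=False).to_frame().to_csv(
        OUT / "dormancy_scores.tsv", sep="\t"
    )
    dormancy = select_dormancy_set(pair)
    qio.write_gmt([dormancy], OUT / "dormancy_set.gmt")

    truth = pd.read_csv(DATA / "study1" / "gene_truth.tsv", sep="\t", index_col=0)["category"]
    planted = set(truth.index[truth.isin(["decreasing", "dormancy"])])
    tp = len(dormancy.members & planted)
    print(
        f"dormancy set: {len(dormancy.members)} genes at score > 2 "
        f"({tp} of {len(planted)} planted program genes; "
        f"precision {tp / len(dormancy.members):.2f})"
    )

    ranked = preranked_vector(pair)
    rows = []
    for cat in ["decreasing", "dormancy", "peak", "late"]:
        members = frozenset(truth.index[truth == cat])
        res = gsea_permutation(ranked, GeneSet(cat, members), n_perm=2000, seed=0)
        rows.append(
            {"set_name": cat, "es": res.es, "nes": res.nes, "p_value": res.p_value}
        )
        print(f"GSEA {cat:<11} ES={res.es:+.3f} NES={res.nes:+.2f} p={res.p_value:.2e}")
    pd.DataFrame(rows).to_csv(OUT / "gsea_planted_sets.tsv", sep="\t", index=False)


if __name__ == "__main__":
    sys.exit(main())
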