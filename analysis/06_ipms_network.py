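#!/usr/bin/env python
"""IP-MS bait-prey specificity and the weighted interaction network.

Applies the identification thresholds (protein probability > 0.99, >= 2
peptides above 0.95), derives the presence matrix, extracts preys pulled
down by all four pathway baits (MMUT, MMAA, MMAB, MCEE) but never by a
negative control (EV, VLCAD), runs per-protein ANOVA across the MMUT/EV/VLCAD
triplicates, and assembles the -log10(p)-weighted network.
"""

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from mmaomics.cohort import BAIT_ROLES
from mmaomics.ipms import (
    anova_enrichment,
    apply_id_thresholds,
    build_network,
    specific_prey,
    venn_partition,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ids = pd.read_csv(ROOT / "cohort" / "ipms_ids.tsv", sep="\t")
    quant = pd.read_csv(ROOT / "cohort" / "ipms_quant.tsv", sep="\t", index_col="protein")

    pm = apply_id_thresholds(ids, bait_roles=BAIT_ROLES)
    flat = pm.detected.copy()
    flat.columns = [f"{b}_r{r}" for b, r in flat.columns]
    flat.reset_index().to_csv(ROOT / "presence_matrix.tsv", sep="\t", index=False)

    preys = specific_prey(pm, {"MMUT", "MMAA", "MMAB", "MCEE"}, 4, {"EV", "VLCAD"})
    print(
        f"{len(preys)} preys pulled down by all of MCEE, MMAA, MMAB and MMUT "
        f"but not by EV or VLCAD in any replicate"
    )
    three_of_four = specific_prey(pm, {"MMUT", "MMAA", "MMAB", "MCEE"}, 3, {"EV", "VLCAD"})
    print(f"{len(three_of_four)} preys under the >= 3-of-4 bait rule")

    regions = venn_partition(pm, ["MMUT", "MMAA", "MMAB", "MCEE"])
    pd.DataFrame(
        [
            {"region": "&".join(sorted(k)), "n_proteins": len(v)}
            for k, v in sorted(regions.items(), key=lambda kv: "&".join(sorted(kv[0])))
        ]
    ).to_csv(ROOT / "venn_regions.tsv", sep="\t", index=False)

    groups = {
        "MMUT": [f"MMUT_r{r}" for r in (1, 2, 3)],
        "EV": [f"EV_r{r}" for r in (1, 2, 3)],
        "VLCAD": [f"VLCAD_r{r}" for r in (1, 2, 3)],
    }
    enr = anova_enrichment(np.log2(quant), groups)
    enr.to_csv(ROOT / "ipms_anova.tsv", sep="\t", index=False)
    n_sig = int((enr["p_anova"] < 0.05).sum())
    print(f"{n_sig} proteins enriched at nominal ANOVA p < 0.05 (MMUT vs EV/VLCAD)")

    G = build_network(preys, enr, pm)
    nx.write_graphml(G, ROOT / "ipms_network.graphml")
    edges = pd.DataFrame(
        [(u, v, d["weight"]) for u, v, d in G.edges(data=True)],
        columns=["bait", "prey", "weight"],
    ).sort_values(["bait", "prey"], kind="mergesort")
    edges.to_csv(ROOT / "ipms_network_edges.tsv", sep="\t", index=False)
    print(f"network: {G.number_of_nodes()} nodes, {G.number_of_edges()} edges")


if __name__ == "__main__":
    main()
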