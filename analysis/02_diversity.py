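#!/usr/bin/env python
"""Alpha and beta diversity of the simulated communities.

Rarefies to the minimum sample depth, computes per-sample alpha indices
with Kruskal-Wallis group tests, and runs Bray-Curtis / PCoA / PERMANOVA /
ANOSIM across the three stands.  Outputs under results/diversity/.
"""

import json
from pathlib import Path

from fungalnet import diversity, tables

DATA = Path("results/data")
OUT = Path("results/diversity")
SEED = 202


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = tables.read_otu_table(DATA / "otu_table.tsv")
    table = tables.OTUTable(table.counts, table.taxonomy,
                            tables.read_metadata(DATA / "metadata.tsv"))
    depth = int(table.depths().min())
    rarefied = tables.rarefy(table, depth, seed=SEED)
    print(f"rarefied to {depth} reads per sample")

    alpha = diversity.alpha_diversity_frame(rarefied)
    alpha.to_csv(OUT / "alpha_diversity.tsv", sep="\t")
    groups = [m.group for m in rarefied.metadata]
    tests = {}
    for index in ("richness", "shannon", "simpson", "chao1"):
        h, p = diversity.kruskal_wallis(alpha[index].to_numpy(), groups)
        tests[index] = {"H": h, "p": p}
        print(f"alpha {index}: Kruskal-Wallis H={h:.2f} p={p:.3f}")

    dm = diversity.bray_curtis(rarefied)
    dm.to_frame().to_csv(OUT / "bray_curtis.tsv", sep="\t")
    coords, explained = diversity.pcoa(dm)
    coords.iloc[:, :3].to_csv(OUT / "pcoa_coordinates.tsv", sep="\t")
    print(f"PCoA axes 1-2 explain {100 * explained[:2].sum():.1f}% of variation")

    f, fp = diversity.permanova(dm, groups, n_perm=999, seed=SEED)
    r, rp = diversity.anosim(dm, groups, n_perm=999, seed=SEED)
    pairwise = diversity.pairwise_anosim(dm, groups, n_perm=999, seed=SEED)
    pairwise.to_csv(OUT / "pairwise_anosim.tsv", sep="\t", index=False)
    with open(OUT / "beta_tests.json", "w") as fh:
        json.dump({"alpha_kw": tests,
                   "permanova": {"F": f, "p": fp},
                   "anosim": {"R": r, "p": rp}}, fh, indent=2, sort_keys=True)
    print(f"PERMANOVA F={f:.2f} p={fp:.4f}; ANOSIM R={r:.3f} p={rp:.4f}")
    print("group separation is driven by the planted phylum profiles")


if __name__ == "__main__":
    main()
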