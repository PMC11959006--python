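#!/usr/bin/env python
"""Composition shifts between stands: phylum-level group tests and
volcano-style differential OTUs (fold change > 4, p < 0.05).

Outputs under results/composition/.
"""

from pathlib import Path

from fungalnet import compare, tables

DATA = Path("results/data")
OUT = Path("results/composition")
SEED = 303


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = tables.read_otu_table(DATA / "otu_table.tsv")
    table = tables.OTUTable(table.counts, table.taxonomy,
                            tables.read_metadata(DATA / "metadata.tsv"))
    rarefied = tables.rarefy(table, int(table.depths().min()), seed=SEED)

    phylum = tables.aggregate_by_rank(rarefied, "phylum")
    kw = compare.group_test_by_taxon(phylum, mode="three-group-KW")
    compare.differential_frame(kw).to_csv(OUT / "phylum_kw.tsv", sep="\t",
                                          index=False)
    sig = [r.feature_id for r in kw if r.status != "ns"]
    print(f"phyla differing across stands (FDR<0.05): {sig}")

    for a, b in (("FN", "SN"), ("FN", "TN"), ("SN", "TN")):
        res = compare.volcano_differential(rarefied, a, b)
        compare.differential_frame(res).to_csv(
            OUT / f"volcano_{b}-{a}.tsv", sep="\t", index=False)
        up = sum(r.status == "enriched" for r in res)
        down = sum(r.status == "decreased" for r in res)
        print(f"{b} vs {a}: {up} OTUs enriched, {down} decreased "
              f"(FC>4, p<0.05)")


if __name__ == "__main__":
    main()
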