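taxon	taxonomicLevel	trophicMode	guild	confidenceRanking
Penicillium	genus	Saprotroph	Undefined Saprotroph	Probable
Aspergillus	genus	Saprotroph	Undefined Saprotroph	Probable
Chaetomium	genus	Saprotroph	Undefined Saprotroph	Probable
Talaromyces	genus	Saprotroph	Undefined Saprotroph	Probable
Xylaria	genus	Saprotroph	Wood Saprotroph	Probable
Preussia	genus	Saprotroph	Dung Saprotroph	Probable
Verticillium	genus	Pathotroph	Plant Pathogen	Probable
Alternaria	genus	Pathotroph	Plant Pathogen	Probable
Botrytis	genus	Pathotroph	Plant Pathogen	Highly Probable
Tuber	genus	Symbiotroph	Ectomycorrhizal	Highly Probable
Cenococcum	genus	Symbiotroph	Ectomycorrhizal	Highly Probable
Oidiodendron	genus	Symbiotroph	Ericoid Mycorrhizal	Probable
Coprinellus	genus	Saprotroph	Undefined Saprotroph	Highly Probable
Trametes	genus	Saprotroph	Wood Saprotroph	Highly Probable
Trichosporon	genus	Saprotroph	Soil Saprotroph	Probable
Mycena	genus	Saprotroph	Litter Saprotroph	Probable
Russula	genus	Symbiotroph	Ectomycorrhizal	Highly Probable
Inocybe	genus	Symbiotroph	Ectomycorrhizal	Highly Probable
Laccaria	genus	Symbiotroph	Ectomycorrhizal	Highly Probable
Tomentella	genus	Symbiotroph	Ectomycorrhizal	Highly Probable
Puccinia	genus	Pathotroph	Plant Pathogen	Highly Probable
Ustilago	genus	Pathotroph	Plant Pathogen	Highly Probable
Exobasidium	genus	Pathotroph	Plant Pathogen	Highly Probable
Mortierella	genus	Saprotroph	Undefined Saprotroph	Probable
Mucor	genus	Saprotroph	Undefined Saprotroph	Probable
Umbelopsis	genus	Saprotroph	Undefined Saprotroph	Probable
Rhizopus	genus	Saprotroph	Undefined Saprotroph	Probable
Endogone	genus	Symbiotroph	Ectomycorrhizal	Probable
Jimgerdemannia	genus	Symbiotroph	Ectomycorrhizal	Probable
Choanephora	genus	Pathotroph	Plant Pathogen	Probable
Fusarium	genus	Pathotroph-Saprotroph	Plant Pathogen-Undefined Saprotroph	Probable
Rhizoctonia	genus	Pathotroph-Saprotroph	Plant Pathogen-Undefined Saprotroph	Probable
Phoma	genus	Pathotroph-Saprotroph	Plant Pathogen-Undefined Saprotroph	Possible
Ganoderma	genus	Pathotroph-Saprotroph	Plant Pathogen-Wood Saprotroph	Probable
Armillaria	genus	Pathotroph-Saprotroph	Plant Pathogen-Wood Saprotroph	Highly Probable
Clonostachys	genus	Pathotroph-Saprotroph	Fungal Parasite-Undefined Saprotroph	Probable
Fusarium oxysporum	species	Pathotroph	Plant Pathogen	Highly Probable
Agaricomycetes	class	Saprotroph	Undefined Saprotroph	Possible
Archaeorhizomycetes	class	Saprotroph	Soil Saprotroph	Possible
Pezizomycetes	class	Saprotroph	Undefined Saprotroph	Possible
Mucoromycota	phylum	Saprotroph	Undefined Saprotroph	Possible
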