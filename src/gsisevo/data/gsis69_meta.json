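{
  "fixture": "gsis69",
  "description": "69 human-mouse orthologue pairs from the core glucose-stimulated insulin secretion (GSIS) network of the pancreatic beta-cell, with sub-pathway membership, phylogenetic age class, human-mouse percent similarity, positive-selection episodes and OMIM disease associations.",
  "genome_reference_proportions": {"U": 0.56, "E": 0.20, "M": 0.05, "V": 0.19},
  "genome_reference_note": "Proportions of Universal / Eukaryote-specific / Metazoan-specific / Vertebrate-specific genes in the whole metabolic complement of the human genome, used as the null for the composition test.",
  "excluded_transporters": {
    "Q4A5HQ1": "pyruvate carrier",
    "O43837": "isocitrate dehydrogenase NAD+ beta",
    "Q00325": "phosphate carrier",
    "Q59GB0": "aspartate/glutamate carrier",
    "P12236": "ATP/ADP carrier"
  },
  "excluded_transporters_note": "Five mouse membrane-transport proteins of the source kinetic model whose human orthologues could not be unambiguously identified; they are excluded from the 69-record set.",
  "genome_panel": {"prokaryote": 219, "nonmetazoan_eukaryote": 24},
  "genome_panel_note": "The homology searches behind the phylogenetic classification covered 243 fully sequenced genomes: 197 Bacteria + 22 Archaea (prokaryote) and 24 Eukaryota."
}
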