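transactions: demo/inputs/transactions.csv
ppi: demo/inputs/ppi.tsv
annotations: demo/inputs/annotations.tsv
compound_targets: demo/inputs/compound_targets.tsv
disease_genes: demo/inputs/disease_genes.txt
gmt_kegg: demo/inputs/gene_sets.gmt
ppi_min_confidence: 0.7
min_support: 0.1
min_confidence: 0.3
seed: 1
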