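cohort:
  background_zipf_exponent: 0.5
  core_herbs:
  - huangqi
  - danshen
  - fuling
  herb_universe_size: 120
  mean_rx_size: 6
  n_case: 300
  n_control: 300
  rr_target: 3.0
  sd_rx_size: 2
  specific_base_prob: 0.08
  specific_herbs:
  - qumai
  - niuxi
molecular:
  herb_ids:
  - huangqi
  - danshen
  - fuling
  - qumai
  - niuxi
  n_compounds: 50
  n_disease_genes: 40
  n_proteins: 300
  n_terms: 15
  ppi_density: 0.03
  term_size: 15
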