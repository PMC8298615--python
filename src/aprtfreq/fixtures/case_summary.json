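{
  "n_cases_total": 482,
  "n_molecular": 311,
  "n_case_alleles_total": 576,
  "n_variants_total": 62,
  "n_observed_in_databases": 29
}
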