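{
  "screened": 235999,
  "males": 123101,
  "females": 112898,
  "initial_positive": 1985,
  "recalled_tested": 1939,
  "recall_positive": 326,
  "confirmed": 12,
  "confirmed_males": 8,
  "confirmed_females": 4,
  "ohp_threshold_nmol_per_l": 12.0
}
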