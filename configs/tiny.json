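{
  "n_parcels": 60,
  "n_subjects": 5,
  "n_conditions": 6,
  "blocks_per_condition": 2,
  "block_len_s": 12.0,
  "rest_len_s": 12.0,
  "tr_s": 0.72,
  "rest_n_tr": 600,
  "acf_max_lag": 40,
  "n_surrogates": 100,
  "n_boot": 100
}
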