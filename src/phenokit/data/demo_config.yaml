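# Demo end-to-end run: simulate both network dialects, harmonize them
# through the shipped catalog and mapping, and analyze leafing-out onsets.
seed: 1
simulate:
  n_plants: 60
  years: [2000, 2001, 2002, 2003, 2004, 2005, 2006, 2007, 2008, 2009]
  status_cadence: 7
  onset_sd: 5.0
  fraction_agricultural: 0.05
analysis:
  require_class: "true_leaf_presence:present"
  exclude_class: "senescing_true_leaf_presence:present"
  genus: Acer
  min_records: 10
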