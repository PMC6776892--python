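# Strong-effect synthetic study: high enrichment, low dispersion, large
# planted effects; the switch report should equal the planted truth exactly.
sim:
  n_chroms: 2
  chrom_length_bp: 5000000
  n_states: 2
  replicates_per_mark: 2
  n_genes: 400
  enrichment_factor: 10.0
  n_common_domains: 20
  n_state_specific_domains: 10
  domain_width_bp: 10000
  library_size: 200000
  de_log2fc: 2.5
  switch_log2fc: 3.0
  nb_dispersion: 0.02
  n_sensitive_genes: 30
  n_switch_genes: [3, 2]
  seed: 7
seed: 7
state_a: UT
state_b: TR
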