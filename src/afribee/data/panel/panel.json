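{
  "coi_reference_fasta": "coi_reference_synthetic.fasta",
  "spacer_exemplars_fasta": "spacer_exemplars_synthetic.fasta",
  "diagnostic_position_mtdna": 2382,
  "coi_fragment_start_mtdna": 1977,
  "restriction_motif": "AGATCT",
  "note": "Synthetic stand-in panel. Substitute real COI and A/C/M/O spacer references to type real specimens."
}
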