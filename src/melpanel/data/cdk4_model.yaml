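symbol: CDK4
chrom: chr12
strand: '-'
sequence_offset: 58145000
isoforms:
- name: CDK4-201
  exons:
  - - 58145000
    - 58145500
  cds_start: 61
  cds_end: 363
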