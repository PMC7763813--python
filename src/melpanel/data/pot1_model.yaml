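symbol: POT1
chrom: chr7
strand: '-'
sequence_offset: 124462000
isoforms:
- name: POT1-201
  exons:
  - - 124462000
    - 124462600
  cds_start: 51
  cds_end: 353
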