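symbol: MITF
chrom: chr3
strand: +
sequence_offset: 69788000
isoforms:
- name: MITF-201
  exons:
  - - 69788000
    - 69789200
  cds_start: 51
  cds_end: 1010
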