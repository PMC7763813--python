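symbol: BAP1
chrom: chr3
strand: '-'
sequence_offset: 52435000
isoforms:
- name: BAP1-201
  exons:
  - - 52435000
    - 52435600
  cds_start: 51
  cds_end: 353
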