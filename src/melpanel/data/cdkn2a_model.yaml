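symbol: CDKN2A
chrom: chr9
strand: '-'
sequence_offset: 21968050
isoforms:
- name: p16
  exons:
  - - 21974677
    - 21974876
  - - 21970901
    - 21971207
  - - 21968101
    - 21968241
  cds_start: 51
  cds_end: 521
- name: p12
  exons:
  - - 21974545
    - 21974876
  cds_start: 51
  cds_end: 299
- name: p16γ
  exons:
  - - 21974677
    - 21974876
  - - 21970901
    - 21971207
  - - 21968571
    - 21968770
  - - 21968101
    - 21968241
  cds_start: 51
  cds_end: 557
- name: p14
  exons:
  - - 21994138
    - 21994430
  - - 21970901
    - 21971207
  - - 21968101
    - 21968241
  cds_start: 101
  cds_end: 499
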