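gene	positive_patients
CDKN2A	98
MITF	10
CDK4	9
BAP1	9
POT1	2
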