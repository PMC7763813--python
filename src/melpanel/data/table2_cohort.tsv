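section	field	low	high
referred	patients	538	350
referred	males	254	180
referred	females	284	170
referred	onset_age_mean	47	47
referred	onset_age_sd	14	15
referred	other_cancer	50	48
carriers	patients	36	92
carriers	males	11	42
carriers	females	25	50
carriers	onset_age_mean	44	41
carriers	onset_age_sd	13	14
carriers	other_cancer	2	9
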