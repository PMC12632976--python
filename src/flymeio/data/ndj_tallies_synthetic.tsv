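genotype	regular_females	regular_males	diplo_X	nullo_X	n_parent_females
control	942	942	1	1	13
cpsf5_rnai	549	549	14	14	15
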