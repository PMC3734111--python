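sample_id	tissue	life_stage	replicate
adult_salivary_gland	adult_salivary_gland	adult	1
larval_salivary_gland	larval_salivary_gland	larval	1
adult_midgut	adult_midgut	adult	1
larval_midgut	larval_midgut	larval	1
adult_tubule	adult_tubule	adult	1
larval_tubule	larval_tubule	larval	1
adult_hindgut	adult_hindgut	adult	1
larval_hindgut	larval_hindgut	larval	1
brain	brain	adult	1
testis	testis	adult	1
whole_fly	whole_fly	whole	1
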