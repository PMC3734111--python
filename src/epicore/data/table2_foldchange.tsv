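probe_id	gene_symbol	adult_salivary_gland	adult_midgut	adult_tubule	adult_hindgut	larval_salivary_gland	larval_midgut	larval_tubule	larval_hindgut	description
Bowl	Bowl	14.8	3.2	10.8	7.1	10.9	5.6	11.5	5.5	transcription factor
bru-2	bru-2	5.6	3.1	8.8	5.9	2.9	2.9	6.9	8.3	RNA binding, translation regulation
Cdep	Cdep	6	4.9	4.9	3.7	4.0	4.4	5.9	4.9	Rho exchange factor activity
CHKov1	CHKov1	18.4	3.9	3.7	3.7	7.5	5.2	3.0	5.1	RNA-directed DNA polymerase
Cyp12e1#1	Cyp12e1	2.8	4.4	5.3	2.8	10.9	9.1	12.1	5.5	Cytochrome P450, E-class, group I
Cyp12e1#2	Cyp12e1	2.8	4.9	5.1	4.4	12.7	8.9	20.3	6.4	Cytochrome P450, E-class, group I
Cyp9c1	Cyp9c1	3.8	3.9	8.5	7.3	7.1	9.12	10.1	16.9	Cytochrome P450, E-class, group I
Drip	Drip	63.1	3.79	8.2	5.6	5.9	3.7	10	14.6	Aquaporin, water channel
Hr39	Hr39	10.3	3.7	9.9	4.8	7.5	7.5	13	8.3	transcription factor, Zinc finger
l(1)G0168	l(1)G0168	20.5	2.4	3.5	3.6	17.6	4.0	6.2	4.8	protein targeting to Golgi
Lola	Lola	5.9	3.3	8.7	6.9	6.7	2.3	3.9	5.2	transcription factor, Zinc finger
Mitf	Mitf	5.3	3.0	2.8	4	6.7	3.1	2.8	4.7	Transcription factor, helix-loop-helix
Msp-300	Msp-300	2.9	4	2.9	4.5	5.3	7.4	4.7	5.9	Actin binding
mthl3	mthl3	2.2	3.1	11.3	3.6	12.7	18	56.7	41.2	G-protein coupled receptor activity
mthl4	mthl4	3.7	3.5	15.6	5.6	24.8	4.8	8.3	7.9	G-protein coupled receptor activity
Nhe1	Nhe1	10.5	2.4	5.9	3.1	14	2.9	4.1	2.8	Na+/H+ exchanger
Ome	Ome	8.6	8.9	4.2	5.5	6.2	7.2	4.6	5.7	dipeptidyl-peptidase
Pvr	Pvr	13.1	3.4	5.8	3.7	4.9	2.5	2.7	3.2	tyrosine kinase
Scrib	Scrib	5.1	7.8	6.3	4.3	4.3	9.9	15.3	5.5	septate junction, cell polarity
Smox	Smox	2.3	2.4	12.8	3.1	2.5	4.6	4.7	3.9	protein binding, axon guidance
Snoo	Snoo	2.8	2.8	5.3	3.1	5.4	3.1	4.9	3.9	negative regulation of dpp signaling
Syb	Syb	2.6	4.1	2.5	3.9	3.0	4.1	4.5	3.1	vesicle-mediated transport
Traf-like	Traf-like	2.9	14.8	14.1	4.3	3	20.6	26.3	6.7	defence response
Troll	Troll	23.7	3.7	5.9	6	3.9	7.5	5.9	4.2	EGF-like, epithelial polarity
unc-115	unc-115	4.9	3.9	2.9	4.5	4.5	3.6	3.2	4.5	actin binding, villin; Zinc finger
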