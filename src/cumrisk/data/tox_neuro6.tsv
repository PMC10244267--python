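chemical	endpoint	species	effect_class	pod_value_ug_kg_bw_d	pod_type	route	oral_bioavailability	factors
Cd	neuro6	mouse	B	200	NOAEL	oral		100:interspecies toxicokinetic/toxicodynamic
Pb	neuro6	human	A	0.5	BMDL01	oral		10:margin of exposure for low risk
iAs	neuro6	human	B	3	NOAEL	oral
MeHg	neuro6	human	A	1.3	TWI	oral
Ni	neuro6	rat	A	500	NOAEL	intraperitoneal	0.05	100:interspecies toxicokinetic/toxicodynamic;3:short study duration
Ni	neuro6	rat	A	1000	LOAEL	intraperitoneal	0.05	100:interspecies toxicokinetic/toxicodynamic;3:short study duration;3:LOAEL to NOAEL extrapolation
Al	neuro6	mouse	A	10000	NOAEL	oral		100:interspecies toxicokinetic/toxicodynamic
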