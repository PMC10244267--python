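chemical	endpoint	species	effect_class	pod_value_ug_kg_bw_d	pod_type	route	oral_bioavailability	factors
Al	neuro_dtu	various	A	100	DTD	oral
Pb	neuro_dtu	various	A	0.05	DTD	oral
MeHg	neuro_dtu	various	A	0.19	DTD	oral
Cd	kidney	various		0.36	DTD	oral
Pb	kidney	various		0.06	DTD	oral
iHg	kidney	various		0.6	DTD	oral
Ni	kidney	various		330	DTD	oral
Al	fertility	various		270	DTD	oral
Pb	fertility	various		0.4	DTD	oral
iHg	fertility	various		1.2	DTD	oral
MeHg	fertility	various		5.0	DTD	oral
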