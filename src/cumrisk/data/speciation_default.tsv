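parent_element	species	food_category	fraction	passthrough
As	iAs	fish	0.02	0
As	iAs	crustaceans_mollusks	0.035	0
As	iAs	water	1.0	0
As	iAs	rice	1.0	1
As	iAs	other	0.70	0
Hg	MeHg	fish	1.0	0
Hg	MeHg	crustaceans_mollusks	0.8	0
Hg	MeHg	water	0.0	0
Hg	MeHg	other	0.0	0
Hg	iHg	fish	0.0	0
Hg	iHg	crustaceans_mollusks	0.2	0
Hg	iHg	water	1.0	0
Hg	iHg	other	1.0	0
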