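# Standard HPO frequency-class terms mapped to patient-fraction intervals.
# version: hpo-frequency-subontology-2024
term	name	lo	hi
HP:0040280	Obligate	1.0	1.0
HP:0040281	Very frequent	0.80	0.99
HP:0040282	Frequent	0.30	0.79
HP:0040283	Occasional	0.05	0.29
HP:0040284	Very rare	0.01	0.04
HP:0040285	Excluded	0.0	0.0
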