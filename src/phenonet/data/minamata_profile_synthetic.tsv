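# Minamata-disease query profile — SYNTHETIC STAND-IN.
# The intellectual-disability frequency (0.37%), the patient count (269) and
# the presence of the spasticity and hypotonia terms are pinned; every other
# frequency is a synthetic placeholder drawn once from a seeded Beta(2,2)
# generator (numpy default_rng seed 20260929).  Replace with a file digitized
# from the original 1970s survey for real analyses.
# label: Minamata disease (diagnosed, Minamata area; synthetic stand-in)
# n_patients: 269
symptom_label	term	frequency
Sensory disturbance of extremities	HP:0003401	0.6954
Ataxia	HP:0001251	0.9396
Gait disturbance	HP:0001288	0.1735
Constriction of peripheral visual field	HP:0001133	0.5934
Hearing impairment	HP:0000365	0.4515
Dysarthria	HP:0001260	0.6832
Tremor	HP:0001337	0.5783
Spasticity	HP:0001257	0.4088
Hypotonia	HP:0001252	0.4292
Mental retardation	HP:0001249	0.0037
Muscle weakness	HP:0001324	0.4251
Hyperreflexia	HP:0001347	0.5418
Nystagmus	HP:0000639	0.6643
Dysphagia	HP:0002015	0.582
Memory impairment	HP:0002354	0.5866
Involuntary movements	HP:0004305	0.129
Excessive salivation	HP:0003781	0.9127
Insomnia	HP:0100785	0.4568
Irritability	HP:0000737	0.7567
Headache	HP:0002315	0.4167
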