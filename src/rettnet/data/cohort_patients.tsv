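Patient	Developmental Regression	Developmental Delay	Intellectual Disability	Microcephaly	Loss of Hand Use	Stereotyped Hand Movements	Involuntary Tongue Movements	Hyperventilation	Choreoathetosis	Early Epileptic Encephalopathy	Hypotonia	Scoliosis	Gene	Protein	Variant: Genomic Coordinates	cDNA Change	Protein Change	Gene-Diseases Association	CADD PHRED Score
1	Y	Y	Y	Y	N	N	N	N	N	Y	Y	N	GABRG2	Gamma-Aminobutyric Acid Type A Receptor Gamma2 Subunit	5:161522557	c.316 G>A	p.Ala106Thr	Epilepsy, generalized, with febrile seizures plus, type 3	22.2
2	N	Y	Y	Y	N	N	N	Y	Y	N	Y	N	GRIN1	Glutamate Ionotropic Receptor NMDA Type Subunit 1	9:140058120	c.2443 G>C	p.Gly815Arg	Mental retardation, autosomal dominant 8	34
3	Y	Y	Y	Y	Y	Y	N	N	Y	Y	Y	N	ATP1A2	ATPase Na+/K+ Transporting Subunit Alpha 2	1:160097570	c.977 T>G	p.Ile326Arg	Alternating hemiplegia of childhood	26.2
4	N	Y	Y	N	N	N	N	N	Y	Y	N	N	KCNQ2	Potassium Voltage-Gated Channel Subfamily Q Member 2	20:63442482	c.740 C>A	p.Ser247Ter	Epileptic encephalopathy, early infantile, 7	41
5	Y	Y	Y	N	N	N	N	N	N	N	N	N	KCNB1	Potassium Voltage-Gated Channel Subfamily B Member 1	20:47991181	c.916 C>T	p.Arg306Cys	Epileptic encephalopathy, early infantile, 26	32
6	N	Y	N	N	N	Y	N	N	Y	N	N	Y	GRIN2A	Glutamate Ionotropic Receptor NMDA Type Subunit 2A	16:9923446	c.1845 T>C	p.Asn614Ser	Epilepsy, focal, with speech disorder and with or without mental retardation	25.6
7	Y	Y	Y	Y	Y	Y	Y	Y	N	N	Y	N	TCF4	Transcription Factor 4	chr18:52901774	c.1486+5 G>T	IVS16+5 G>T (Splice Variant)	Pitt-Hopkins	23.4
8	N	Y	Y	Y	N	Y	N	N	N	N	Y	N	SEMA6B	Semaphorin 6B	chr19:4544288	c.1991delG	p.G664AfsX21	Autism Spectrum Disorder	16.8
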