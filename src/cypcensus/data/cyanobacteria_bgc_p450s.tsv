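p450_name	cluster_types	most_similar_known	similarity_percent
CYP213A8	T3PKS	Xenocyloins	25
CYP213A5	bacteriocin
CYP213A6	T3PKS	Colicin V	2
CYP110AH1	NRPS	Anabaenopeptin NZ 857/nostamide A	100
CYP213A3	bacteriocin
CYP120C2	T2PKS	Ambiguine	6
CYP110K6	NRPS
CYP120A21	bacteriocin
CYP110Q3	NRPS, T1PKS	Hapalosin	40
CYP110C17	terpene
CYP110C29	NRPS, T1PKS	Nostophycin	27
CYP1011G1	NRPS, T1PKS	Crocacin	23
CYP110AP1	terpene
CYP110AT1	NRPS, T1PKS	Hapalosin	40
CYP110Q4	NRPS, T1PKS	Hapalosin	40
CYP110C21	NRPS-like	Anacyclamide	14
CYP197E3	NRPS, T1PKS	Cryptophycin	37
CYP110AG1	terpene	Hectochlorin	25
CYP110E29	terpene, thiopeptide, T1PKS, NRPS	Nostophycin	27
CYP110E18	terpene, thiopeptide, T1PKS, NRPS	Nostophycin	27
CYP110C21	terpene
CYP110Q4	NRPS, T1PKS	Puwainaphycins	40
CYP110AT1	NRPS, T1PKS	Puwainaphycins	40
CYP120A13	ladderane
CYP1185A1	lassopeptide, bacteriocin
CYP110Q2	NRPS, T1PKS	Hapalosin	40
CYP110C14	terpene	6,6′-oxybis(2,4-dibromophenol)	14
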