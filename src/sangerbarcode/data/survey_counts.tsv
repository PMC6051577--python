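group	item	count	denominator
survey	samples_total	187	187
survey	below_threshold	19	187
survey	novel_published	12	187
survey	excluded_low_quality	7	187
survey	genera	87	187
survey	haplotypes	98	187
animals	samples	70	70
animals	phylum_Arthropoda	63	70
animals	class_Insecta	47	70
animals	order_Hymenoptera	30	70
animals	order_Diptera	9	70
animals	class_Malacostraca	14	70
animals	species_level	49	70
plants	samples	116	116
plants	order_Asterales	32	116
plants	order_Poales	28	116
plants	order_Rosales	12	116
plants	order_Caryophyllales	12	116
plants	species_level	49	116
plants	species_level_Asterales	14	32
plants	species_level_Poales	11	28
fungi	samples	1	1
fungi	species_level	1	1
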