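# SYNTHETIC assay metadata: representative per-species constants for the
# demo and the simulation studies.  1C genome masses are plausible
# plant-genome values of the right order of magnitude, NOT curated
# database entries; real analyses should supply their own table with
# C-values and target copy numbers for the assays actually used.
species	genome_size_1c_pg	ploidy	target_copies_per_haploid	class_label
Origanum vulgare	0.96	2	1	ingredient
Origanum onites	0.96	2	1	ingredient
Olea europaea	1.42	2	1	adulterant
Myrtus communis	0.45	2	1	adulterant
Cistus incanus	2.00	2	1	adulterant
Origanum majorana	0.95	2	1	adulterant
Rhus coriaria	0.70	2	1	adulterant
Convolvulus arvensis	0.75	2	1	contaminant
Chenopodium album	1.60	6	1	contaminant
Corylus avellana	0.48	2	1	contaminant
Thymus vulgaris	0.60	2	1	contaminant
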