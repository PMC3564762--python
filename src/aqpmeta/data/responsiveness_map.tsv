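# Responsiveness map: per-gene regulation codes over (cue, tissue) groups of comparisons.
# Codes: '-' no regulation (FC<1.5); 'C' consistent regulation (FC>=1.5 in 100% of comparisons, one direction);
# integer = number of regulated comparisons (intermediate); 'x' = both up- and down-regulations observed.
# Tissues: L leaf, R root, X xylem, B bark, St stem, Lb leaf bud, Fb floral bud, Ca callus, SC suspension cells.
# The cue-to-column alignment was reconstructed from the running text; codes and counts are verbatim.
group	abiotic_stress	abiotic_stress	abiotic_stress	abiotic_stress	abiotic_stress	abiotic_stress	abiotic_stress	abiotic_stress	abiotic_stress	abiotic_stress	abiotic_stress	abiotic_stress	nutrition	nutrition	nutrition	nutrition	nutrition	hormone	hormone	hormone	hormone	biotic	biotic	temporal_oscillation	temporal_oscillation	temporal_oscillation	temporal_oscillation	temporal_oscillation
cue	water_deficit	water_deficit	water_deficit	osmoticum	salt	salt	hypoxia	wounding	wounding	aluminium	embolism_infiltration	embolism_infiltration	starvation	starvation	gln	glc	gln_glc	cim	sim	meja	ga_modified	pathogen	mycorrhiza	seasonal	seasonal	seasonal	diurnal	diurnal
tissue	L	X	R	R	X	R	R	L	L	R	R	X	L	B	B	B	B	St	Ca	SC	R	L	R	Lb	Fb	St	L	X
n_comparisons	40	1	6	1	2	3	3	1	3	1	3	2	6	3	2	2	2	2	2	1	5	4	2	3	4	1	18	4
PtNIP1;1	x	C	2	C	1	x	-	-	2	C	-	-	2	1	1	-	C	1	-	-	1	2	-	1	3	-	x	-
PtNIP1;2	x	-	3	C	-	-	C	-	x	-	-	-	4	-	-	-	-	-	-	-	3	1	-	2	-	-	x	-
PtNIP1;3	1	-	-	-	-	-	-	C	-	-	-	-	-	1	C	-	-	-	-	-	-	-	-	-	-	-	-	-
PtNIP1;4	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
PtNIP2;1	x	-	4	-	-	2	x	-	2	-	1	-	x	-	-	-	-	-	-	-	-	1	-	-	-	-	x	-
PtNIP3;1	x	-	-	-	-	1	-	-	1	-	-	-	-	x	1	-	C	C	-	-	-	-	-	-	-	-	-	-
PtNIP3;2	x	-	1	-	-	1	-	-	-	C	1	-	x	2	C	-	C	C	-	-	1	-	-	C	-	-	1	-
PtNIP3;3	x	C	x	C	C	2	2	-	x	-	-	1	C	C	-	-	-	C	-	C	4	1	1	C	-	-	x	2
PtNIP3;4	x	-	x	-	1	C	2	-	-	C	1	1	2	C	-	-	1	1	C	-	-	-	1	C	3	-	7	2
PtNIP3;5	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
PtPIP1;1	x	-	3	C	-	-	-	-	x	-	-	1	2	1	-	-	-	x	1	C	1	-	-	C	3	-	7	1
PtPIP1;2	x	C	-	C	1	1	C	-	2	-	1	1	x	1	-	-	-	1	1	C	4	1	1	2	1	-	x	1
PtPIP1;3	x	C	-	-	-	-	-	-	x	-	-	-	-	-	-	-	-	C	1	-	-	-	-	1	-	-	5	-
PtPIP1;4	x	C	3	C	1	2	-	-	-	C	C	1	x	C	1	-	C	C	C	-	-	-	1	2	3	-	x	-
PtPIP1;5	x	C	4	-	-	2	2	-	1	-	1	-	x	C	C	-	C	x	-	-	-	1	-	-	2	-	x	1
PtPIP2;1	x	-	1	C	C	-	2	-	1	-	1	1	-	2	-	-	1	C	-	-	-	-	-	x	3	-	x	-
PtPIP2;2	x	-	3	C	C	x	1	-	1	-	1	-	3	-	-	1	1	C	1	-	-	3	1	C	2	C	x	-
PtPIP2;3	x	C	-	-	1	-	C	-	1	-	1	-	3	2	1	-	1	C	-	C	1	1	-	C	-	-	x	-
PtPIP2;4	x	-	2	C	1	-	-	-	x	-	2	C	x	2	-	-	1	-	-	-	4	1	-	2	x	C	x	-
PtPIP2;5	x	C	4	-	1	2	-	-	2	-	1	1	2	2	1	-	C	x	1	-	C	-	1	-	-	C	x	1
PtPIP2;6	x	C	-	C	1	1	-	-	2	-	1	1	4	1	-	-	1	x	C	C	3	2	-	x	2	-	x	1
PtPIP2;7	x	C	C	C	1	2	C	-	1	-	x	C	3	x	1	-	-	1	C	-	C	1	1	x	1	-	x	1
PtPIP2;8	x	-	5	C	1	-	C	-	x	-	-	-	2	2	C	-	C	1	C	-	4	-	-	C	1	-	x	1
PtPIP2;9	x	-	-	-	-	-	-	-	1	-	-	-	3	1	-	-	1	C	C	-	-	2	-	C	3	-	x	-
PtPIP2;10	x	-	5	C	-	x	C	-	x	C	1	-	2	2	-	x	1	1	1	-	2	1	1	-	1	C	x	-
PtSIP1;1	-	-	-	C	-	-	-	-	-	-	-	-	-	C	-	-	-	-	-	-	-	-	-	C	3	-	-	-
PtSIP1;2	x	C	3	-	C	-	2	-	2	-	1	1	1	C	-	-	-	-	-	-	2	1	-	C	1	-	x	-
PtSIP1;3	x	C	2	-	1	1	2	-	1	-	-	-	-	C	1	-	1	1	-	-	-	-	1	C	1	C	x	-
PtSIP1;4	x	-	-	C	-	1	1	-	-	-	-	-	x	-	C	-	C	1	C	-	-	-	1	1	1	-	3	-
PtSIP2;1	x	C	-	C	-	-	1	C	2	C	-	-	-	1	-	-	C	x	C	-	-	2	-	C	1	-	x	-
PtSIP2;2	-	-	2	-	-	-	x	-	-	-	-	-	1	-	-	-	-	x	C	C	2	1	-	-	-	-	-	-
PtTIP1;1	x	C	4	C	1	C	C	-	2	C	-	1	3	-	1	1	1	1	C	-	C	-	x	-	-	C	x	2
PtTIP1;2	-	C	5	C	1	C	C	-	-	-	1	C	-	-	-	-	-	-	-	-	C	-	x	-	-	C	-	2
PtTIP1;3	x	-	C	-	-	C	2	-	x	-	-	1	4	x	-	-	C	C	C	C	C	1	1	C	2	-	14	2
PtTIP1;4	x	C	C	C	1	C	-	-	x	-	-	C	5	C	1	-	1	C	C	-	C	1	x	-	3	-	x	2
PtTIP1;5	x	C	1	C	1	2	C	-	x	-	-	-	3	C	C	1	C	C	1	-	1	2	1	2	1	-	x	1
PtTIP1;6	x	C	-	-	1	1	C	-	2	-	-	-	4	C	1	-	-	C	-	C	2	3	1	1	1	-	x	-
PtTIP1;7	x	-	1	C	-	-	2	-	2	-	-	1	3	1	-	-	-	C	1	-	C	1	-	C	1	C	x	-
PtTIP1;8	x	-	-	-	-	2	C	-	C	-	2	-	5	C	C	1	C	C	x	-	C	1	1	C	1	-	x	-
PtTIP2;1	x	-	C	C	-	C	1	-	1	-	-	1	x	2	C	-	-	C	1	-	1	3	1	C	-	-	x	-
PtTIP2;2	x	C	C	C	1	-	-	-	x	C	1	-	1	C	C	-	1	C	1	-	1	1	-	x	-	-	x	2
PtTIP2;3	-	-	4	C	-	1	1	-	-	-	-	-	-	-	-	-	-	-	-	-	C	-	-	-	-	-	-	-
PtTIP2;4	-	-	4	C	-	C	1	-	-	-	1	-	-	-	-	-	-	-	-	-	C	-	1	-	-	-	-	-
PtTIP3;1	-	-	-	-	-	-	-	-	-	-	-	-	1	-	-	-	-	-	-	C	-	-	-	-	-	-	-	-
PtTIP3;2	x	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	1	-
PtTIP4;1	x	C	1	-	1	C	C	-	x	-	-	1	3	C	-	-	-	C	x	-	-	1	-	C	1	-	x	-
PtTIP5;1	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
PtTIP5;2	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
PtXIP1;2	-	C	C	C	-	2	-	-	1	-	1	-	-	-	-	-	-	-	-	-	-	-	C	-	-	-	-	-
PtXIP1;3	-	-	4	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
PtXIP1;4	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	C	-	-
PtXIP1;5	x	-	-	-	-	-	-	-	2	-	-	-	x	-	-	-	C	C	C	-	-	2	-	C	1	C	x	-
PtXIP2;1	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
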