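family	species	chrom_class	locus_id	has_introns	mechanism_hint
EIF1A	human	X	EIF1AX	True	unknown
EIF1A	chimpanzee	X	EIF1AX	True	unknown
EIF1A	gorilla	X	EIF1AX	True	unknown
EIF1A	orangutan	X	EIF1AX	True	unknown
EIF1A	rhesus	X	EIF1AX	True	unknown
EIF1A	baboon	X	EIF1AX	True	unknown
EIF1A	marmoset	X	EIF1AX	True	unknown
EIF1A	squirrel_monkey	X	EIF1AX	True	unknown
EIF1A	mouse	X	EIF1AX	True	unknown
EIF1A	rat	X	EIF1AX	True	unknown
EIF1A	cattle	X	EIF1AX	True	unknown
EIF1A	human	Y	EIF1AY	True	unknown
EIF1A	chimpanzee	Y	EIF1AY	True	unknown
EIF1A	gorilla	Y	EIF1AY	True	unknown
EIF1A	orangutan	Y	EIF1AY	True	unknown
EIF1A	rhesus	Y	EIF1AY	True	unknown
EIF1A	baboon	Y	EIF1AY	True	unknown
EIF1A	marmoset	Y	EIF1AY	True	unknown
EIF1A	squirrel_monkey	Y	EIF1AY	True	unknown
EIF1A	cattle	Y	EIF1AY	True	unknown
EIF1A	mouse	A	EIF1A_rA	False	retro
EIF1A	rat	A	EIF1A_rA	False	retro
EIF1A	cattle	A	EIF1A_bA	False	retro
EIF2S3	human	X	EIF2S3X	True	unknown
EIF2S3	chimpanzee	X	EIF2S3X	True	unknown
EIF2S3	gorilla	X	EIF2S3X	True	unknown
EIF2S3	orangutan	X	EIF2S3X	True	unknown
EIF2S3	rhesus	X	EIF2S3X	True	unknown
EIF2S3	baboon	X	EIF2S3X	True	unknown
EIF2S3	marmoset	X	EIF2S3X	True	unknown
EIF2S3	squirrel_monkey	X	EIF2S3X	True	unknown
EIF2S3	mouse	X	EIF2S3X	True	unknown
EIF2S3	rat	X	EIF2S3X	True	unknown
EIF2S3	cattle	X	EIF2S3X	True	unknown
EIF2S3	mouse	Y	EIF2S3Y	True	unknown
EIF2S3	rat	Y	EIF2S3Y	True	unknown
EIF2S3	cattle	Y	EIF2S3Y	True	unknown
EIF2S3	human	A	EIF2S3_apeA	False	retro
EIF2S3	chimpanzee	A	EIF2S3_apeA	False	retro
EIF2S3	gorilla	A	EIF2S3_apeA	False	retro
EIF2S3	orangutan	A	EIF2S3_apeA	False	retro
EIF2S3	rhesus	A	EIF2S3_owmA	False	retro
EIF2S3	baboon	A	EIF2S3_owmA	False	retro
EIF2S3	marmoset	A	EIF2S3_nwmA	False	retro
EIF2S3	squirrel_monkey	A	EIF2S3_nwmA	False	retro
EIF2S3	cattle	A	EIF2S3_bA	False	retro
RPS4	human	X	RPS4X	True	unknown
RPS4	chimpanzee	X	RPS4X	True	unknown
RPS4	gorilla	X	RPS4X	True	unknown
RPS4	orangutan	X	RPS4X	True	unknown
RPS4	rhesus	X	RPS4X	True	unknown
RPS4	baboon	X	RPS4X	True	unknown
RPS4	marmoset	X	RPS4X	True	unknown
RPS4	squirrel_monkey	X	RPS4X	True	unknown
RPS4	mouse	X	RPS4X	True	unknown
RPS4	rat	X	RPS4X	True	unknown
RPS4	cattle	X	RPS4X	True	unknown
RPS4	opossum	X	RPS4X	True	unknown
RPS4	wallaby	X	RPS4X	True	unknown
RPS4	human	Y	RPS4Y	True	unknown
RPS4	chimpanzee	Y	RPS4Y	True	unknown
RPS4	gorilla	Y	RPS4Y	True	unknown
RPS4	orangutan	Y	RPS4Y	True	unknown
RPS4	rhesus	Y	RPS4Y	True	unknown
RPS4	baboon	Y	RPS4Y	True	unknown
RPS4	marmoset	Y	RPS4Y	True	unknown
RPS4	squirrel_monkey	Y	RPS4Y	True	unknown
RPS4	mouse	A	RPS4_rA	False	retro
RPS4	rat	A	RPS4_rA	False	retro
RPS4	opossum	A	RPS4_m1A	False	retro
RPS4	wallaby	A	RPS4_m1A	False	retro
RPS4	opossum	A	RPS4_m2A	False	retro
RPS4	wallaby	A	RPS4_m2A	False	retro
RPS4	cattle	A	RPS4_bA	False	retro
UBA1	human	X	UBA1X	True	unknown
UBA1	chimpanzee	X	UBA1X	True	unknown
UBA1	gorilla	X	UBA1X	True	unknown
UBA1	orangutan	X	UBA1X	True	unknown
UBA1	rhesus	X	UBA1X	True	unknown
UBA1	baboon	X	UBA1X	True	unknown
UBA1	marmoset	X	UBA1X	True	unknown
UBA1	squirrel_monkey	X	UBA1X	True	unknown
UBA1	mouse	X	UBA1X	True	unknown
UBA1	rat	X	UBA1X	True	unknown
UBA1	cattle	X	UBA1X	True	unknown
UBA1	opossum	X	UBA1X	True	unknown
UBA1	wallaby	X	UBA1X	True	unknown
UBA1	mouse	Y	UBA1Y	True	unknown
UBA1	rat	Y	UBA1Y	True	unknown
UBA1	squirrel_monkey	Y	UBA1Y	True	unknown
UBA1	opossum	Y	UBA1Y	True	unknown
UBA1	wallaby	Y	UBA1Y	True	unknown
UBA1	marmoset	A	UBA1_mA	True	dna
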