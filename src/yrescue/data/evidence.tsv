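family	species	locus_id	orf_status	transcribed	recency	omega	expression_pattern
EIF1A	mouse	EIF1A_rA	intact	True	keep	0.0010	broad
EIF1A	rat	EIF1A_rA	intact	True	keep	0.0010	broad
EIF1A	cattle	EIF1A_bA	truncated	False	keep		silent
EIF2S3	human	EIF2S3_apeA	intact	True	keep	0.075	testis_specific
EIF2S3	chimpanzee	EIF2S3_apeA	intact	True	keep		testis_specific
EIF2S3	gorilla	EIF2S3_apeA	intact	True	keep		testis_specific
EIF2S3	orangutan	EIF2S3_apeA	intact	True	keep		testis_specific
EIF2S3	rhesus	EIF2S3_owmA	intact	True	keep		testis_specific
EIF2S3	baboon	EIF2S3_owmA	intact	True	keep		testis_specific
EIF2S3	marmoset	EIF2S3_nwmA	intact	True	keep		broad
EIF2S3	squirrel_monkey	EIF2S3_nwmA	intact	True	keep		broad
EIF2S3	cattle	EIF2S3_bA	truncated	False	keep		silent
RPS4	mouse	RPS4_rA	intact	True	keep	0.0059	testis_specific
RPS4	rat	RPS4_rA	intact	True	keep	0.0059	testis_specific
RPS4	opossum	RPS4_m1A	intact	True	keep	0.0132	broad
RPS4	wallaby	RPS4_m1A	intact	True	keep	0.0132	broad
RPS4	opossum	RPS4_m2A	intact	True	keep	0.0053	broad
RPS4	wallaby	RPS4_m2A	intact	True	keep	0.0053	broad
RPS4	cattle	RPS4_bA	intact	True	keep	0.0180	testis_specific
UBA1	marmoset	UBA1_mA	intact	True	keep	0.3381	testis_specific
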