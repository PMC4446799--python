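family	species	locus_id	upstream_flanks	downstream_flanks
EIF1A	mouse	EIF1A_rA	Rnf114,Snai1	Ube2v1,Tmem189
EIF1A	rat	EIF1A_rA	Rnf114,Snai1	Ube2v1,Tmem189
EIF1A	cattle	EIF1A_bA	LOCB1,LOCB2	LOCB3,LOCB4
EIF2S3	human	EIF2S3_apeA	APG1,APG2	APG3,APG4
EIF2S3	chimpanzee	EIF2S3_apeA	APG1,APG2	APG3,APG4
EIF2S3	gorilla	EIF2S3_apeA	APG1,APG2	APG3,APG4
EIF2S3	orangutan	EIF2S3_apeA	APG1,APG2	APG3,APG4
EIF2S3	rhesus	EIF2S3_owmA	OWG1,OWG2	OWG3,OWG4
EIF2S3	baboon	EIF2S3_owmA	OWG1,OWG2	OWG3,OWG4
EIF2S3	marmoset	EIF2S3_nwmA	NWG1,NWG2	NWG3,NWG4
EIF2S3	squirrel_monkey	EIF2S3_nwmA	NWG1,NWG2	NWG3,NWG4
EIF2S3	cattle	EIF2S3_bA	BEG1,BEG2	BEG3,BEG4
RPS4	mouse	RPS4_rA	RRG1,RRG2	RRG3,RRG4
RPS4	rat	RPS4_rA	RRG1,RRG2	RRG3,RRG4
RPS4	opossum	RPS4_m1A	MG1A,MG1B	MG1C,MG1D
RPS4	wallaby	RPS4_m1A	MG1A,MG1B	MG1C,MG1D
RPS4	opossum	RPS4_m2A	MG2A,MG2B	MG2C,MG2D
RPS4	wallaby	RPS4_m2A	MG2A,MG2B	MG2C,MG2D
RPS4	cattle	RPS4_bA	BRG1,BRG2	BRG3,BRG4
UBA1	marmoset	UBA1_mA	UBA1Y_F1,UBA1Y_F2	UBA1Y_F3,UBA1Y_F4
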