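code	breed	n_offspring	n_families	country	method	purebred
KKH	Kooikerhondje	17	10	Finland	sequencing	1
SA	Saluki	51	16	Finland	sequencing	1
LW	Lowchen	9	4	Finland	sequencing	1
ISD	Icelandic Sheepdog	7	3	Finland	sequencing	1
KL	Kromfohrlander	90	24	Finland	sequencing	1
AH1	Alaskan Husky	27	6	USA	sequencing	1
AH2	Alaskan Husky	4	1	USA	sequencing	1
ECS	English Cocker Spaniel	6	1	USA	sequencing	1
GR	Golden Retriever	7	3	USA	sequencing	1
SBT	Staffordshire Bull Terrier	7	3	USA	sequencing	1
NF	Newfoundland	42	12	UK	sequencing	1
RRB	Rhodesian Ridgeback	42	5	UK	sequencing	1
CB2	Mixed-breed	84	16	USA	sequencing	0
CB1	Mixed-breed	37	6	USA	sequencing_or_microsatellite	0
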