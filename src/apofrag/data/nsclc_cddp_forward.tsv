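accession	gene	peptides	ratio	mwcal_da	mwexp_lo_kda	mwexp_hi_kda
P53634	CTSC	6	3.5849	51,854	15	20
Q9Y4W6	AFG3L2	2	2.7856	88,584	15	20
O75844	ZMPSTE24	2	100	54,813	15	20
Q5VTE0	EEF1A1P5	2	1.7272	50,185	15	20
P63261	ACTG1	2	5.4425	41,793	5	10
O95197	RTN3	2	2.3429	112,611	15	20
Q9NQC3	RTN4	1	100	129,931	15	20
Q92504	SLC39A7	1	11.5738	50,118	15	20
P07686	HEXB	1	2.9101	63,111	15	20
Q16891	IMMT	1	100	83,678	15	20
Q86UE4	MTGH	1	100	63,837	5	10
Q8IZ41	RASEF	1	23.1859	82,879	5	10
P05141	SLC25A5	1	45.9929	32,852	5	10
Q8NGV7	OR5H2	1	1.01	35,974	5	10
P07602	PSAP	1	3.1506	58,133	5	10
P07339	CTSD	1	2.8517	44,552	5	10
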