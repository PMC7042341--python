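accession	gene	peptides	ratio	mwcal_da	mwexp_lo_kda	mwexp_hi_kda
P53634	CTSC	4	8.096	51,854	15	20
Q9NX40	OCIAD1	3	100	27,626	5	10
P63261	ACTG1	3	21.9962	41,793	5	10
Q8NGV7	OR5H2	2	100	35,974	5	10
P12236	SLC25A6	2	100	32,866	5	10
Q8IZ41	RASEF	1	1.9371	82,879	25	30
Q9BQE3	TUBA1C	1	100	49,895	5	10
Q9P0L0	VAPA	1	100	27,893	5	10
Q9Y230	RUVBL2	1	100	51,157	5	10
Q86UE4	MTDH	1	100	63,837	5	10
P07602	PSAP	1	18.9825	58,113	5	10
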