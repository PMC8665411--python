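feature_id	protein_id	gene_symbol	level	log2_fc	se	raw_p	adj_p	n_peptides_used	n_obs_removed_outlier	detect_reps_a	detect_reps_b	specific_flag
BG01	BG01	BG01	protein	0.229182	0.142354	0.12234	0.370774	2	0	4	8	none
BG02	BG02	BG02	protein	0.257935	0.135931	0.0715917	0.334095	2	0	4	8	none
BG03	BG03	BG03	protein	-0.0768743	0.109396	0.489949	0.650285	2	0	4	8	none
BG04	BG04	BG04	protein	-0.040324	0.155017	0.7973	0.858631	2	0	4	8	none
BG05	BG05	BG05	protein	0.00627647	0.120067	0.958804	0.958804	2	0	4	8	none
BG06	BG06	BG06	protein	-0.110158	0.135859	0.42656	0.650285	2	0	4	8	none
BG07	BG07	BG07	protein	-0.0347505	0.118275	0.771787	0.858631	2	0	4	8	none
BG08	BG08	BG08	protein	-0.200776	0.128253	0.132419	0.370774	2	0	4	8	none
BG09	BG09	BG09	protein	-0.146045	0.148365	0.336145	0.650285	2	0	4	8	none
BG10	BG10	BG10	protein	-0.106585	0.159379	0.510938	0.650285	2	0	4	8	none
DWN1	DWN1	DWN1	protein	-2.04356	0.106132	3.67064e-19	5.13889e-18	3	0	4	8	none
NUL1	NUL1	NUL1	protein	0.0541156	0.0776308	0.490781	0.650285	3	0	4	8	none
NUL2	NUL2	NUL2	protein	-0.11231	0.117219	0.360591	0.650285	1	0	4	8	none
SPA1	SPA1	SPA1	protein	NA	NA	NA	NA	0	0	4	0	a_only
SPB1	SPB1	SPB1	protein	NA	NA	NA	NA	0	0	0	8	b_only
UPQ1	UPQ1	UPQ1	protein	1.81294	0.103846	6.47358e-18	4.53151e-17	3	0	4	8	none
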