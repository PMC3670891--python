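case_id	histotype	msi_status	ESCO1	CHTF18	MRE11A	ATAD5
T79	serous	stable	1	1	0	1
T113	clear cell	stable	1	0	0	1
T77	clear cell	unstable	1	0	0	0
T88	endometrioid	unstable	1	1	0	0
T68	serous	stable	0	0	1	0
T3	serous	stable	0	0	1	1
T51	serous	stable	0	0	0	1
T62	serous	stable	0	0	0	1
X001	serous	stable	0	0	0	0
X002	serous	stable	0	0	0	0
X003	serous	stable	0	0	0	0
X004	serous	stable	0	0	0	0
X005	serous	stable	0	0	0	0
X006	serous	stable	0	0	0	0
X007	serous	stable	0	0	0	0
X008	serous	stable	0	0	0	0
X009	serous	stable	0	0	0	0
X010	serous	stable	0	0	0	0
X011	serous	stable	0	0	0	0
X012	serous	stable	0	0	0	0
X013	serous	stable	0	0	0	0
X014	serous	stable	0	0	0	0
X015	serous	stable	0	0	0	0
X016	serous	stable	0	0	0	0
X017	serous	stable	0	0	0	0
X018	serous	stable	0	0	0	0
X019	serous	stable	0	0	0	0
X020	serous	stable	0	0	0	0
X021	serous	stable	0	0	0	0
X022	serous	stable	0	0	0	0
X023	serous	stable	0	0	0	0
X024	serous	stable	0	0	0	0
X025	serous	stable	0	0	0	0
X026	serous	stable	0	0	0	0
X027	serous	stable	0	0	0	0
X028	serous	stable	0	0	0	0
X029	serous	stable	0	0	0	0
X030	serous	stable	0	0	0	0
X031	serous	stable	0	0	0	0
X032	serous	stable	0	0	0	0
X033	serous	stable	0	0	0	0
X034	serous	stable	0	0	0	0
X035	serous	stable	0	0	0	0
X036	serous	stable	0	0	0	0
X037	serous	stable	0	0	0	0
X038	serous	stable	0	0	0	0
X039	serous	stable	0	0	0	0
X040	serous	stable	0	0	0	0
X041	clear cell	stable	0	0	0	0
X042	clear cell	stable	0	0	0	0
X043	clear cell	stable	0	0	0	0
X044	clear cell	stable	0	0	0	0
X045	clear cell	stable	0	0	0	0
X046	clear cell	stable	0	0	0	0
X047	clear cell	stable	0	0	0	0
X048	clear cell	stable	0	0	0	0
X049	clear cell	stable	0	0	0	0
X050	clear cell	stable	0	0	0	0
X051	clear cell	stable	0	0	0	0
X052	clear cell	stable	0	0	0	0
X053	clear cell	stable	0	0	0	0
X054	clear cell	stable	0	0	0	0
X055	clear cell	stable	0	0	0	0
X056	clear cell	stable	0	0	0	0
X057	clear cell	stable	0	0	0	0
X058	clear cell	stable	0	0	0	0
X059	endometrioid	stable	0	0	0	0
X060	endometrioid	stable	0	0	0	0
X061	endometrioid	stable	0	0	0	0
X062	endometrioid	stable	0	0	0	0
X063	endometrioid	stable	0	0	0	0
X064	endometrioid	stable	0	0	0	0
X065	endometrioid	stable	0	0	0	0
X066	endometrioid	stable	0	0	0	0
X067	endometrioid	stable	0	0	0	0
X068	endometrioid	stable	0	0	0	0
X069	endometrioid	stable	0	0	0	0
X070	endometrioid	stable	0	0	0	0
X071	endometrioid	stable	0	0	0	0
X072	endometrioid	stable	0	0	0	0
X073	endometrioid	stable	0	0	0	0
X074	endometrioid	stable	0	0	0	0
X075	endometrioid	stable	0	0	0	0
X076	endometrioid	stable	0	0	0	0
X077	endometrioid	stable	0	0	0	0
X078	endometrioid	stable	0	0	0	0
X079	endometrioid	stable	0	0	0	0
X080	endometrioid	stable	0	0	0	0
X081	endometrioid	stable	0	0	0	0
X082	endometrioid	stable	0	0	0	0
X083	endometrioid	stable	0	0	0	0
X084	endometrioid	stable	0	0	0	0
X085	endometrioid	stable	0	0	0	0
X086	endometrioid	stable	0	0	0	0
X087	endometrioid	stable	0	0	0	0
X088	endometrioid	stable	0	0	0	0
X089	endometrioid	stable	0	0	0	0
X090	endometrioid	stable	0	0	0	0
X091	endometrioid	stable	0	0	0	0
X092	endometrioid	stable	0	0	0	0
X093	endometrioid	stable	0	0	0	0
X094	endometrioid	stable	0	0	0	0
X095	endometrioid	stable	0	0	0	0
X096	endometrioid	stable	0	0	0	0
X097	endometrioid	stable	0	0	0	0
X098	endometrioid	stable	0	0	0	0
X099	endometrioid	stable	0	0	0	0
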