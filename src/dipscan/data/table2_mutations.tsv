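case_id	gene	histotype	msi_status	cdna_change	protein_change	mutation_type	predicted_assessor	predicted_sift	predicted_polyphen
T79	ESCO1	serous	stable	c.G1012T	p.E338X	nonsense	n/a	n/a	n/a
T113	ESCO1	clear cell	stable	c.G1075A	p.D359N	missense	Low	Tolerated	Benign
T77	ESCO1	clear cell	unstable	c.C1595T	p.S532L	missense	Low	Tolerated	Probably damaging
T88	ESCO1	endometrioid	unstable	c.C2356T	p.R786C	missense	Medium	Affects function	Probably damaging
T79	CHTF18	serous	stable	c.G2035A	p.D679N	missense	Low	Tolerated	Probably damaging
T88	CHTF18	endometrioid	unstable	c.C2560T	p.R854W	missense	Medium	Tolerated	Possibly damaging
T68	MRE11A	serous	stable	c.G2074T	p.D692Y	missense	Low	Affects function	Probably damaging
T3	MRE11A	serous	stable	c.G1448A	p.R483Q	missense	Low	Tolerated	Benign
T3	MRE11A	serous	stable	c.G391A	p.D131N	missense	Medium	Affects function	Possibly damaging
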