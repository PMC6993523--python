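gene_id	wt_testis_mean	gcf_testis_mean	annotation
106568506	248942.4	71175.8	dsl1l (gsdf)
106575603	21784.4	24951.3	inha
106561951	12028.3	21845.6	ctsl
106580334	2616.9	7858.6	nodal
106585325	2658.0	1028.6	bmp6l
106585642	2649.9	1021.4	bmp6l
106610757	357.3	843.9	Uncharacterized ncRNA
106561959	247.0	463.1	ctssl
106600069	634.1	202.9	Slc25a12l
106609789	698.5	171.8	Uncharacterized
106578524	145.7	125.1	Uncharacterized
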