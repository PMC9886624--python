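rsid	effect_allele	other_allele	beta	gene_label	proxy_rsid	proxy_r2	proxy_allele_map
rs10745742	T	C	0.017	AMDHD1	rs6538691	0.99	T=T,C=C
rs12785878	T	G	0.036	DHCR7
rs10741657	A	G	0.031	CYP2R1
rs17216707	T	C	0.026	CYP24A1
rs8018720	C	G	-0.017	SEC23A
rs2282679	T	C	-0.089	GC
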