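time_bp	hgvs_c	hgvs_p	rsid	position	variation_type	locations	carriers
32823	c.409C>T	p.(Arg137*)	rs730881701	exonic	stopgain	Russia, Italy	2
10000	c.1375+1G>A	p.(=)	rs759706360	splicing	-	Brazil	1
8315	c.433C>T	p.(Arg145Trp)	rs137853007	exonic	nonsynonymous	Turkey, Sudan, China	3
7963	c.31C>T	p.(Gln11*)	rs1349961118	exonic	stopgain	Ukrayina, Mongolia	2
7480	c.291G>A	p.(Trp97*)	rs2054312626	exonic	stopgain	Finland, Mongolia	2
6856	c.1297C>T	p.(Gln433*)	rs1555913494	exonic	stopgain	Russia	1
6713	c.319+1G>A	p.(=)	rs765080766	splicing	-	Russia, Ukraine	2
6415	c.205C>T	p.(Gln69*)	rs768384031	exonic	stopgain	Chile	1
6386	c.625C>T	p.(Gln209*)	rs1569149953	exonic	stopgain	Russia, Croatia	2
6238	c.683+1G>A	p.(=)	rs786203650	splicing	-	Russia	1
4503	c.1315C>T	p.(Gln439*)	rs778989252	exonic	stopgain	Russia	1
4498	c.100C>T	p.(Gln34*)	rs1231012263	exonic	stopgain	China	1
4462	c.1555C>T	p.(Arg519*)	rs200432447	exonic	stopgain	Mongolia, China	2
4272	c.279G>A	p.(Trp93*)	rs587782070	exonic	stopgain	Russia	1
3681	c.1461+2T>C	p.(=)	rs779844113	splicing	-	Denmark	1
3626	c.232C>T	p.(Gln78*)	rs1555932341	exonic	stopgain	Russia	1
3556	c.151C>T	p.(Gln51*)	rs587781592	exonic	stopgain	Sweden	1
3435	c.283C>T	p.(Arg95*)	rs587781269	exonic	stopgain	Turkey, Russia, Czech, China	4
3328	c.1095+1G>A	p.(=)	rs768172525	splicing	-	Turkey, Russia	2
3000	c.908+2T>C	p.(=)	rs1601752066	splicing	-	Russia	1
2064	c.592+1G>A	p.(=)	rs1601822722	splicing	-	Turkey, Russia	2
1988	c.1528C>T	p.(Gln510*)	rs886039512	exonic	stopgain	Russia	1
1646	c.85C>T	p.(Gln29*)	rs761494650	exonic	stopgain	Turkey, Russia	2
450	c.341G>A	p.(Trp114*)	rs1555927374	exonic	stopgain	Turkey	1
372	c.1050del	p.(Glu351Argfs*14)	rs2052610542	exonic	deletion	Italy	1
NA	c.79C>T	p.(Gln27*)	rs376736188	exonic	stopgain	Turkey	1
NA	c.1009-1G>A	p.(=)	rs1555914382	splicing	-	Turkey	1
NA	c.1486C>T	p.(Gln496*)	rs756250205	exonic	stopgain	Turkey	1
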