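species	mya	gene	hgvs_c	hgvs_p
Orangutan	15.2	PMS2	c.803+1G>A	p.(Tyr268*)
Gibbon	19.5	TP53	c.537T>A	p.(His179Gln)
Gibbon	19.5	TP53	c.489C>A	p.(Tyr163*)
Gibbon	19.5	DNA2	c.593G>A	p.(Arg198His)
Rhesus	28.8	ATM	c.3994-159A>G	p.(=)
Rhesus	28.8	TP53	c.887A>G	p.(His296Arg)
Crab-eating macaque	28.8	ATM	c.3994-159A>G	p.(=)
Crab-eating macaque	28.8	FANCA	c.14G>A	p.(Trp5*)
Crab-eating macaque	28.8	TP53	c.887A>G	p.(His296Arg)
Baboon	28.8	TP53	c.887A>G	p.(His296Arg)
Baboon	28.8	BRCA1	c.3122C>G	p.(Ser1041*)
Green monkey	28.8	ATM	c.3994-159A>G	p.(=)
Green monkey	28.8	BRCA2	c.9501G>A	p.(=)
Green monkey	28.8	FANCA	c.2982-192A>G	p.(=)
Green monkey	28.8	TP53	c.887A>G	p.(His296Arg)
Marmoset	38	ATM	c.3994-159A>G	p.(=)
Marmoset	38	ATM	c.2341C>T	p.(Gln781*)
Marmoset	38	BRCA2	c.1642C>T	p.(Gln548*)
Marmoset	38	MLH1	c.208-3C>T	p.(=)
Marmoset	38	TP53	c.887A>G	p.(His296Arg)
Marmoset	38	BRCA1	c.850C>T	p.(Gln284*)
Marmoset	38	POLK	c.1284G>A	p.(=)
Squirrel monkey	38	ATM	c.2341C>T	p.(Gln781*)
Squirrel monkey	38	BRCA2	c.1642C>T	p.(Gln548*)
Squirrel monkey	38	BRCA2	c.4689G>A	p.(Trp1563*)
Squirrel monkey	38	FANCA	c.14G>A	p.(Trp5*)
Squirrel monkey	38	MLH1	c.208-3C>T	p.(=)
Squirrel monkey	38	TP53	c.887A>G	p.(His296Arg)
Squirrel monkey	38	POLK	c.1284G>A	p.(=)
Bushbaby	74	ATM	c.3382C>T	p.(Gln1128*)
Bushbaby	74	BRCA2	c.2651C>A	p.(Ser884*)
Bushbaby	74	BRCA2	c.2978G>A	p.(Trp993*)
Bushbaby	74	BRCA2	c.4689G>A	p.(Trp1563*)
Bushbaby	74	BRCA2	c.5263G>T	p.(Glu1755*)
Bushbaby	74	BRCA2	c.5791C>T	p.(Gln1931*)
Bushbaby	74	FANCA	c.3765+2C>T	p.(=)
Bushbaby	74	FANCA	c.2504+134A>G	p.(=)
Bushbaby	74	FANCA	c.2021C>A	p.(Ser674*)
Bushbaby	74	FANCA	c.1567-20A>G	p.(=)
Bushbaby	74	FANCA	c.683C>G	p.(Ala228Gly)
Bushbaby	74	FANCC	c.1490G>A	p.(Trp497*)
Bushbaby	74	MLH1	c.208-3C>T	p.(=)
Bushbaby	74	PMS2	c.1606C>T	p.(Gln536*)
Bushbaby	74	TP53	c.887A>G	p.(His296Arg)
Bushbaby	74	FANCG	c.346C>T	p.(Gln116*)
Bushbaby	74	POLH	c.2074A>G	p.(Thr692Ala)
Bushbaby	74	BRCA1	c.4185+4105C>T	p.(=)
Bushbaby	74	BRCA1	c.1058G>A	p.(Trp353*)
Bushbaby	74	POLK	c.1284G>A	p.(=)
Bushbaby	74	POLK	c.2033C>T	p.(Ser678Phe)
Bushbaby	74	RNASEH2B	c.58G>C	p.(Val20Leu)
Bushbaby	74	PALB2	c.1451T>A	p.(Leu484*)
Bushbaby	74	PALB2	c.1675C>T	p.(Gln559*)
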