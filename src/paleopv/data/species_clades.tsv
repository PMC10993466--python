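species	assembly	clade
human	hg19	Primate
chimp	panTro4	Primate
gorilla	gorGor3	Primate
orangutan	ponAbe2	Primate
gibbon	nomLeu3	Primate
rhesus	rheMac3	Primate
baboon	papAnu2	Primate
marmoset	calJac3	Primate
squirrel_monkey	saiBol1	Primate
bushbaby	otoGar3	Primate
mouse	mm10	Euarchontoglires
rat	rn6	Euarchontoglires
guinea_pig	cavPor3	Euarchontoglires
rabbit	oryCun2	Euarchontoglires
squirrel	speTri2	Euarchontoglires
dog	canFam3	Laurasiatheria
cat	felCat8	Laurasiatheria
horse	equCab2	Laurasiatheria
cow	bosTau8	Laurasiatheria
pig	susScr3	Laurasiatheria
elephant	loxAfr3	Afrotheria
manatee	triMan1	Afrotheria
tenrec	echTel2	Afrotheria
opossum	monDom5	Mammalia
tasmanian_devil	sarHar1	Mammalia
platypus	ornAna1	Mammalia
chicken	galGal4	Aves
zebra_finch	taeGut2	Aves
budgerigar	melUnd1	Aves
coelacanth	latCha1	Sarcopterygii
frog	xenTro7	Sarcopterygii
zebrafish	danRer10	Fish
fugu	fr3	Fish
medaka	oryLat2	Fish
stickleback	gasAcu1	Fish
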