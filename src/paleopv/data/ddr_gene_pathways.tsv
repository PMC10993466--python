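gene	pathways
ATM	DDR_response
ATR	DDR_response
ATRIP	DDR_response
APEX1	BER
APEX2	BER
BARD1	HR
BLM	HR
BRCA1	FA,HR
BRCA2	FA,HR
BRIP1	FA,HR
CHEK1	DDR_response
CHEK2	DDR_response
DCLRE1C	NHEJ
DDB1	NER
DDB2	NER
DNA2	HR,DR
EME1	HR
ERCC1	NER
ERCC2	NER
ERCC3	NER
ERCC4	FA,NER
ERCC5	NER
ERCC6	NER
ERCC8	NER
EXO1	MMR
FAN1	FA
FANCA	FA
FANCB	FA
FANCC	FA
FANCD2	FA
FANCE	FA
FANCF	FA
FANCG	FA
FANCI	FA
FANCL	FA
FANCM	FA
FEN1	BER,DR
GEN1	HR
GTF2H1	NER
GTF2H2	NER
GTF2H3	NER
GTF2H4	NER
GTF2H5	NER
HUS1	DDR_response
LIG1	DR
LIG3	BER
LIG4	NHEJ
MAD2L2	FA
MBD4	BER
MCM2	DR
MCM3	DR
MCM4	DR
MCM5	DR
MCM6	DR
MCM7	DR
MDC1	DDR_response
MLH1	MMR
MLH3	MMR
MPG	BER
MRE11	HR
MSH2	MMR
MSH3	MMR
MSH6	MMR
MUS81	HR
MUTYH	BER
NBN	HR
NEIL1	BER
NEIL2	BER
NEIL3	BER
NHEJ1	NHEJ
NTHL1	BER
OGG1	BER
PALB2	FA,HR
PARP1	BER
PCNA	DR,MMR
PMS1	MMR
PMS2	MMR
POLA1	DR
POLB	BER
POLD1	DR
POLE	DR
POLH	DR
POLK	DR
PRIM1	DR
PRKDC	NHEJ
RAD1	DDR_response
RAD17	DDR_response
RAD50	HR
RAD51	FA,HR
RAD51B	HR
RAD51C	FA,HR
RAD51D	HR
RAD52	HR
RAD54B	HR
RAD54L	HR
RAD9A	DDR_response
RBBP8	HR
REV1	DR
REV3L	DR
RFC1	DR
RFWD3	FA
RNASEH1	DR
RNASEH2A	DR
RNASEH2B	DR
RNASEH2C	DR
SLX4	FA,HR
SMUG1	BER
SSBP1	DR
TDG	BER
TELO2	DDR_response
TOP3A	HR
TOPBP1	DDR_response
TP53	DDR_response
TP53BP1	DDR_response
UBE2T	FA
UIMC1	DDR_response
UNG	BER
WRN	HR
XPA	NER
XPC	NER
XRCC1	BER
XRCC2	FA,HR
XRCC3	HR
XRCC4	NHEJ
XRCC5	NHEJ
XRCC6	NHEJ
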