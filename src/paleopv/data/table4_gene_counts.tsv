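gene	pvs
ATM	147
BRCA2	122
BRCA1	116
FANCA	67
MLH1	66
MSH2	59
TP53	50
PALB2	48
MSH6	46
RAD50	38
MUTYH	33
BRIP1	33
PMS2	32
ERCC6	30
BARD1	28
CHEK2	28
NBN	24
BLM	21
FANCC	17
RAD51D	16
MSH3	15
FANCD2	12
RAD51C	12
XPC	12
ERCC2	11
FANCI	11
FANCG	10
MRE11	10
ERCC3	9
ERCC8	8
RNASEH2B	8
ERCC5	7
RNASEH2A	7
FANCE	6
FANCM	6
NTHL1	6
POLH	5
RAD51	5
XPA	5
ATR	4
DCLRE1C	4
ERCC4	4
LIG4	4
NHEJ1	4
RAD54L	4
RNASEH2C	4
SLX4	4
SSBP1	4
XRCC4	4
ERCC1	3
FAN1	3
RNASEH1	3
TELO2	3
FANCF	2
GTF2H5	2
LIG1	2
LIG3	2
MCM2	2
RBBP8	2
XRCC2	2
MCM7	2
RAD51B	1
DDB2	1
DNA2	1
FANCL	1
MCM5	1
POLD1	1
TOP3A	1
UBE2T	1
UIMC1	1
UNG	1
XRCC1	1
MCM4	1
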