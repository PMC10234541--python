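# REACTOME TLR4-signalling gene set used by ccatlas.dge.signature_test
TLR6
NOD1
TAB1
IRAK3
TIRAP
CHUK
CREB1
ATF2
MAPK14
TICAM1
AGER
DUSP3
DUSP4
DUSP6
DUSP7
ELK1
TAB2
FOS
LY96
PELI3
TAB3
TBK1
HMGB1
APP
TICAM2
IKBKB
IRAK1
IRAK2
IRF3
IRF7
JUN
PEDS-UBE2V1
MEF2A
MEF2C
MAP3K1
MYD88
ATF1
NFKB2
NFKBIA
NFKBIB
IRAK4
ECSIT
PPP2CA
PPP2CB
PPP2R1A
PPP2R1B
PPP2R5D
MAPK1
MAPK3
MAPK7
MAPK8
MAPK11
MAPK9
MAPK10
MAP2K1
MAP2K2
MAP2K3
MAP2K6
MAP2K7
PELI2
PELI1
SIGIRR
RELA
RPS6KA1
RPS6KA2
RPS6KA3
RPS27A
S100A12
S100B
SAA1
NOD2
MAP2K4
MAP3K7
BTK
TLR1
TLR2
TLR3
TLR4
TRAF3
TRAF6
RPS27AP11
UBA52
UBE2N
MAPKAPK3
IKBKG
RIPK1
RIPK2
RPS6KA5
MAPKAPK2
CD14
IKBKE
CDK1
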