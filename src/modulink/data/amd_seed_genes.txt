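# AMDgset: curated genes with reported significant genetic association to
# age-related macular degeneration, transcribed from the source study's
# gene table (176 symbols). ABCA1 and KERA are restored from the same
# study's pathway-membership table; they are omitted from some renderings
# of the gene table but are attested AMDgset members there.
ABCA1
ABCG1
ABCG8
ABHD2
ACAD10
ACE
ADAMTS9
ALDH3A2
ANGPT2
APOE
ARHGAP21
ARMS2
ASPM
B3GLCT
BCO1
BCO2
C2
C20orf85
C3
C4A
C6orf223
C9
CACNG3
CAPN5
CATSPER2
CCL2
CCR2
CCR3
CD36
CD63
CETP
CFB
CFD
CFH
CFHR1
CFHR2
CFHR3
CFHR4
CFHR5
CFI
CLUL1
CNN2
COL10A1
COL15A1
COL4A3
COL8A1
CRP
CST3
CTRB1
CTRB2
CX3CR1
CXCL8
CYP1A2
CYP2R1
CYP46A1
DAPL1
DDR1
ELN
ELOVL4
ERCC2
ERCC6
ESR1
F13B
FADS1
FADS2
FBLN5
FCGR2A
FGD6
FGL1
FILIP1L
FKBPL
FLT1
FPR1
FRK
GAS6
GPX1
GPX3
GRK5
GSTM1
HLA-B
HLA-C
HLA-DQB1
HMCN1
HMOX1
HMOX2
HTRA1
IER3
IGF1R
IL17A
IL17RC
IL1B
KCTD10
KDR
KERA
KMT2E
LIPC
LOXL1
LRP6
MALL
MMP2
MMP20
MMP9
MRPL10
MT2A
MTHFR
MTR
MYRIP
NFE2L2
NOS2
NOS3
NPC1L1
NPHP1
NPLOC4
NQO1
OSBP2
P2RX4
P2RX7
PGF
PILRA
PILRB
PLEKHA1
PON1
PPARG
PPARGC1A
PRKDC
PRKN
PRLR
PTCHD3
RAD51
RAD51B
RDH5
RGS10
RHO
RLBP1
ROBO1
RORA
RORB
RXRA
SCARB1
SELP
SERPINF1
SERPING1
SIRT1
SKIV2L
SLC16A8
SLC44A4
SMUG1
SOD2
SOD3
SPEF2
SRPK2
STRC
SYN3
TF
TFR2
TFRC
TGFBR1
TIMP3
TLR2
TLR3
TLR4
TMEM97
TNF
TNFRSF10A
TNMD
TNXB
TRPM1
TRPM3
TSPAN10
UBE3D
UNG
VDR
VEGFA
VLDLR
VTN
ZBTB41
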