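# Shortest-path candidate genes with seed-pair betweenness > 1000,
# transcribed from the source study's candidate-gene table (42 rows).
gene	betweenness
ABCG5	5123
FASN	4885
C3	4533
CNGB1	3931
PNN	3892
PTPN11	3207
APOA1	2980
NCK1	2640
CAV1	2468
FN1	2421
AP4M1	2330
CD4	2310
PTPN6	2248
ACAN	2218
BANP	2118
TMEM79	2100
F13A1	2073
CLU	2002
ELN	1926
GRK2	1911
RIPK1	1899
LRP1	1885
DHCR7	1862
NCKIPSD	1843
LYN	1698
TF	1591
CACNA1I	1580
FLT1	1501
CEBPB	1458
PTPN13	1426
SLC9A3R1	1413
SLC27A2	1411
PSMA4	1342
CFH	1323
AXL	1289
ATXN3	1261
LGALS3	1143
PRDX1	1112
EZR	1083
VEGFA	1056
FBLN5	1045
ANXA1	1044
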