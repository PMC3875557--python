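# Example five-condition expression panel: log2 fold changes for the hit
# rows of a published deletion-mutant / over-expressor screen. Empty cells
# are measurements that were not available.
gene_id	whi3_glucose	whi3_ethanol	whi3_external	overexp_glucose	overexp_ethanol
PHO84	3.7	0.0	0.2	-0.9	-0.4
RSB1	2.2		1.4	-1.1	-0.3
PHM8	2.5	-0.1	0.9	-1.5	-1.5
YLR346C	2.7	1.2	0.0	-0.5	0.7
DSE4	1.4	0.9	1.3	0.0	-0.5
GTO3	2.0	1.1	0.6	0.0	0.3
FIT2	2.2	0.2	0.3	0.5	-0.6
SPL2	1.9	0.4	0.3	-0.7	-1.1
YGR146C	1.8	1.1	0.3	0.2	-0.6
BDH2	2.3	1.1	-0.3	-0.5	0.0
CHA1	1.1	0.9	0.9	-1.3	-2.4
ATG7	1.2	0.4	0.6	0.1	-0.1
CLB1	1.2	0.9	0.7	-1.2	-0.7
HES1	1.5	0.2	0.3	-0.2	-0.1
GLK1	1.6	0.1	0.2	-0.1	-0.2
MPM1	1.0	0.7	0.7	-0.3	-0.1
SML1	1.0	1.1	0.7	-0.7	-0.4
GDH3	1.4	0.6	0.3	-0.4	0.2
MBF1	1.1	1.0	0.5	-0.5	-0.5
YHR140W	1.2	-0.2	0.5	-0.6	-0.1
AIM17	1.3	0.8	0.3	-0.2	0.4
ICY1	1.1	0.1	0.5	-0.4	-1.0
GPD1	1.4	0.9	0.2	-1.7	-0.6
ENO1	1.3	1.0	0.2	-0.4	-0.5
YOR1	1.2	0.4	0.3	-0.3	-0.1
HSP82	1.1	0.3	0.4	-0.6	-0.2
GLO4	1.2	0.4	0.2	0.2	-0.6
PDR3	1.2	-0.1	0.2	-0.1	-0.1
SNQ2	1.1	0.6	0.3	-0.2	-0.2
PDR15	1.4	0.0	0.0	-0.7	0.0
ICT1	1.1	0.0	0.0	-0.2	0.0
VTC3	1.2	-0.1	-0.2	-0.2	-0.5
CMK2	1.1	0.1	0.0	-0.2	-0.1
YIL100W	1.0	0.7		-0.8	0.7
SAM3	-1.4	-0.5	0.1	0.8	0.4
GDH1	-1.4	-0.2	-0.1	0.3	0.9
MMP1	-1.4	-0.4	-0.1	0.6	-0.1
NDJ1	-1.9		-0.4	0.6	0.2
JHD2	-1.5	-0.2	-0.9	0.5	0.0
POT1	-1.5	-0.6	-1.1	0.8	0.6
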