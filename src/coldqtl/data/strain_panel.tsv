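# Non-synonymous-SNP allele matrix across sequenced S. cerevisiae strains
# (chromosome IV candidate-region genes), transcribed by hand from a published
# strain-panel table. 21 genes, 30 positions, 2 parents + 28 panel strains.
# Transcription notes:
#  - The source table lists a second row named W303 with different alleles;
#    it is kept here as W303-2 so the panel stays at 28 strains.
#  - "." marks a blank cell in the source (unknown allele); the source's "-"
#    cell (LalvinQA23 at SIR2 377845) is likewise recorded as missing.
#  - The NAT1 SNP position is 380252 per the table header; accompanying text
#    gives 380,256. The table value is recorded; analyses key on gene identity.
#  - Gene-to-column spanning in the source is resolved so that exactly the
#    CBS1 (333467) and NAT1 (380252) columns carry parent-unique alleles of
#    the superior parent ZX11(6), as the source text states.
gene	BRE1	BRE1	BRE1	AHK1	AHK1	BDF2	BDF2	CBS1	USO1	MBP1	PSA1	MCH1	SLC1	KNH1	STP4	SIT4	FAD1	SIR2	NAT1	PRM7	PRM7	PRM7	BSC1	BSC1	BSC1	PUS9	PUS9	GPR1	SLM3	DBP10
pos	324262	324892	325302	325321	327540	329181	331087	333467	349698	353161	356771	360451	363194	365865	368078	370101	373080	377845	380252	382330	382655	382829	384900	384944	385473	388147	388851	390756	393487	395873
ZX11(6)	T	A	G	C	A	G	G	T	A	G	A	C	T	G	G	G	C	A	C	G	A	G	T	C	G	G	G	A	G	G
NX9(4)	G	G	A	G	G	C	A	C	T	C	T	T	G	A	C	C	T	G	T	A	G	A	A	T	A	A	A	T	T	A
S288C	T	G	A	C	G	G	G	C	A	G	T	C	G	G	C	G	C	A	T	G	A	G	T	C	A	A	G	A	G	A
AWRI1631	T	A	G	C	A	G	A	C	A	G	T	C	T	G	G	G	C	A	T	G	A	G	T	C	A	G	G	A	G	A
AWRI796	T	A	G	C	A	G	A	C	A	G	A	C	T	G	G	G	C	A	T	G	A	G	T	C	A	G	G	A	G	A
BY4741	T	G	A	C	G	G	G	C	A	G	T	C	G	G	C	G	C	A	T	G	A	G	T	C	A	A	G	A	G	A
BY4742	T	G	A	C	G	G	G	C	A	G	T	C	G	G	C	G	C	A	T	G	A	G	T	C	A	A	G	A	G	A
CBS7960	T	G	A	C	G	G	G	C	A	G	T	C	G	G	C	G	C	A	T	A	G	A	T	C	A	A	G	T	G	A
CEN.PK113	T	G	A	C	G	G	G	C	A	G	A	C	G	G	C	G	C	A	T	G	A	G	T	C	A	A	G	A	G	A
DBVPG6044	T	G	A	C	G	G	G	C	A	G	T	C	G	G	C	G	C	A	T	A	G	G	.	.	A	A	G	T	G	A
DBVPG6765	T	A	G	C	A	G	G	C	A	G	T	C	G	G	C	G	C	A	T	G	A	G	.	C	G	G	G	A	G	G
EC1118	T	G	G	C	A	G	G	C	A	G	T	C	T	G	C	G	C	A	T	G	A	G	T	C	A	A	G	A	G	G
SK1	T	G	A	C	G	G	G	C	A	G	T	C	G	G	C	G	C	A	T	A	G	G	.	.	A	A	G	T	G	A
Sigma1278b	T	G	A	C	G	G	G	C	A	C	T	C	G	G	C	G	T	A	T	G	A	G	.	.	A	A	G	T	G	A
W303	T	G	A	C	G	G	G	C	A	G	A	C	G	G	C	G	C	A	T	A	G	G	A	.	A	A	G	T	G	A
YPS128	T	G	A	C	G	G	G	C	A	G	T	C	G	G	C	G	C	A	T	A	G	A	.	T	A	A	G	T	G	A
YJM269	T	G	A	G	G	G	G	C	A	G	T	C	G	G	C	G	C	A	T	A	G	A	A	C	A	G	G	A	G	A
YJM339	T	G	A	C	G	G	G	C	A	G	A	C	G	G	C	G	C	A	T	A	G	A	A	C	A	A	G	T	G	A
YJM789	T	G	A	C	G	G	G	C	A	G	A	C	G	G	C	G	C	A	T	G	A	G	A	C	A	G	G	A	G	A
Kyokai7	T	G	A	C	G	G	G	C	A	G	A	C	G	G	C	G	C	A	T	A	G	A	T	T	A	A	G	T	G	A
T7	T	G	G	C	G	G	G	C	A	G	A	C	T	G	C	G	C	A	T	G	A	G	T	C	A	A	G	A	G	G
LalvinQA23	T	G	A	C	G	G	A	C	T	C	A	T	G	A	C	C	C	.	T	A	G	A	T	T	A	A	A	A	G	G
RM11-1a	T	G	A	C	G	G	G	C	A	G	A	C	G	G	C	G	C	A	T	G	A	G	T	C	A	A	G	A	G	A
UC5	T	A	G	C	A	G	G	C	A	G	A	C	G	G	C	G	C	A	T	G	A	G	T	C	A	G	G	A	G	G
VL3	T	A	G	C	A	G	A	C	A	G	T	C	G	G	C	G	C	A	T	G	A	G	T	C	G	A	G	A	G	G
Vin13	T	G	G	C	A	G	G	C	A	G	T	C	G	G	C	G	C	A	T	G	A	G	T	C	A	G	G	A	G	A
W303-2	T	A	G	C	A	G	G	C	A	G	T	C	G	G	C	G	C	A	T	G	A	G	T	C	A	A	G	A	G	G
ZTW1	T	G	A	C	G	G	G	C	A	G	A	C	G	G	C	G	C	A	T	G	A	G	T	C	A	A	G	A	G	A
Y12	T	G	A	C	G	G	G	C	A	G	T	C	G	G	C	G	C	A	T	A	G	A	A	T	A	G	G	T	G	A
FostersB	T	.	G	G	A	G	G	.	A	C	T	T	.	G	C	G	C	A	T	A	G	A	T	T	G	A	G	T	G	A
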