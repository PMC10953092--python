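# Per-tumor curated variants (16 tumors, most relevant genes of the curated
# panel), hand-transcribed from the published variant table. Long format:
# one row per (sample, gene, protein change). CRC_15 carries no entry in any
# of the shown columns and therefore has no rows here.
#
# The publisher's flattened table layout makes the gene column of a few
# cells ambiguous. Cells below marked UNCERTAIN were assigned to the single
# gene choice that reproduces every printed per-column tumor count
# (APC 8/16, AMER1 7/16, KRAS 9/16, BRAF 5/16, TP53 6/16, ARID1A 10/16,
# ALK 4/16, somatic MLH1 2/16, somatic PMS2 2/16, germline MLH1 1/16);
# gene-confirmed anchors from the running text (KRAS alleles, BRAF
# p.R356Q/p.R667Q/p.P399L_fs, TP53 p.R175H/p.R273*, MLH1 p.S404Y/p.R497G_fs,
# PMS2 p.E745K/p.T680M, germline MLH1 p.R516W) were fixed first.
# UNCERTAIN cells: CRC_3 TP53 p.M73W_fs; CRC_5 ARID1A p.G875R;
# CRC_7 ARID1A p.A273P_fs; CRC_10 TP53 p.P142L; CRC_13 TP53 p.M73W_fs;
# CRC_16 ALK p.P1408Q_fs.
sample	gene	protein_change	compartment
CRC_1	AMER1	p.F173L_fs	somatic
CRC_1	KRAS	p.Q61R	somatic
CRC_1	ARID1A	p.P1328R_fs	somatic
CRC_1	ARID1A	p.H2020N	somatic
CRC_2	AMER1	p.R630L	somatic
CRC_2	KRAS	p.G12D	somatic
CRC_2	ARID1A	p.A282V	somatic
CRC_2	ARID1A	p.G859E	somatic
CRC_2	ALK	p.R28S	somatic
CRC_2	PMS2	p.E745K	somatic
CRC_3	TP53	p.M73W_fs	somatic
CRC_3	ARID1A	p.Q423K	somatic
CRC_3	ARID1A	p.S748N	somatic
CRC_3	ALK	p.G902R	somatic
CRC_4	APC	p.A2120T	somatic
CRC_4	AMER1	p.Q978*	somatic
CRC_4	KRAS	p.G12S	somatic
CRC_4	KRAS	p.G13D	somatic
CRC_4	BRAF	p.R356Q	somatic
CRC_4	MLH1	p.S404Y	somatic
CRC_5	ARID1A	p.G875R	somatic
CRC_5	MLH1	p.R516W	germline
CRC_6	APC	p.R2759H	somatic
CRC_6	BRAF	p.P399L_fs	somatic
CRC_6	TP53	p.R175H	somatic
CRC_6	MLH1	p.R497G_fs	somatic
CRC_6	PMS2	p.T680M	somatic
CRC_7	APC	p.R1450*	somatic
CRC_7	KRAS	p.A59T	somatic
CRC_7	ARID1A	p.A273P_fs	somatic
CRC_8	APC	p.G721*	somatic
CRC_8	APC	p.T1556N_fs	somatic
CRC_8	KRAS	p.G12D	somatic
CRC_8	ARID1A	p.G771S	somatic
CRC_8	ARID1A	p.P1569L_fs	somatic
CRC_9	AMER1	p.A36V	somatic
CRC_9	AMER1	p.K238N	somatic
CRC_9	AMER1	p.K260N_fs	somatic
CRC_9	AMER1	p.A622P_fs	somatic
CRC_9	KRAS	p.G13D	somatic
CRC_9	KRAS	p.R68W	somatic
CRC_9	BRAF	p.P399L_fs	somatic
CRC_9	TP53	p.M73W_fs	somatic
CRC_9	TP53	p.A119V	somatic
CRC_9	TP53	p.R175H	somatic
CRC_9	TP53	p.R337H	somatic
CRC_9	ARID1A	p.F2142S_fs	somatic
CRC_10	APC	p.L204I	somatic
CRC_10	APC	p.R2721H	somatic
CRC_10	AMER1	p.F173L_fs	somatic
CRC_10	KRAS	p.G12D	somatic
CRC_10	KRAS	p.A146T	somatic
CRC_10	BRAF	p.P399L_fs	somatic
CRC_10	TP53	p.P142L	somatic
CRC_10	ARID1A	p.L2240F	somatic
CRC_10	ARID1A	p.A2238S	somatic
CRC_10	ALK	p.Q500R	somatic
CRC_11	KRAS	p.A146T	somatic
CRC_12	APC	p.A1296T	somatic
CRC_12	APC	p.A1755V	somatic
CRC_12	APC	p.N1792M_fs	somatic
CRC_12	AMER1	p.F173L_fs	somatic
CRC_12	KRAS	p.G12D	somatic
CRC_12	ARID1A	p.R1278*	somatic
CRC_12	ARID1A	p.D1851T_fs	somatic
CRC_13	APC	p.N627L_fs	somatic
CRC_13	AMER1	p.F173L_fs	somatic
CRC_13	BRAF	p.R667Q	somatic
CRC_13	TP53	p.M73W_fs	somatic
CRC_14	APC	p.Y796C	somatic
CRC_14	APC	p.R1687Q	somatic
CRC_14	TP53	p.R273*	somatic
CRC_14	ARID1A	p.P1569L_fs	somatic
CRC_16	ALK	p.P1408Q_fs	somatic
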