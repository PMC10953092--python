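# Clinical cohort table, 24 animals. Hand-transcribed from the published
# staging/grading table; coded values kept exactly as printed ("n.A" = not
# available). TNM digits and grade are single integers; fibrosis pos/neg.
id	sex	age_arrival	age_death	diagnosis_mode	fob	imaging	t_stage	n_stage	m_stage	grade	fibrosis	subtype	localization	comorbidities
CRC_1	m	21.0	21.7	Biopsy	pos	US & CT & FDG-PET	3	1	0	2	pos	AdenoCa	Ileocecal junction, cecocolic junction, metastasis: tumor-assoc. LN	Weight loss, anemia, hypoproteinemia
CRC_2	f	12.3	n.A	Biopsy	pos	US & CT	3	0	0	2	pos	AdenoCa	Ileocecal junction, cecocolic junction	st.p. tumor resection, typhlocolitis
CRC_3	m	19.6	20.8	Necropsy	pos	US & CT	3	0	0	2	pos	AdenoCa	Cecocolic junction	Weight loss, azotemia
CRC_4	f	18.9	20.0	Biopsy	pos	US & CT	4	0	0	1	pos	AdenoCa	Ileocecal junction	Weight loss, anemia, arthritis, thrombocytosis, lipoma
CRC_5	f	22.1	22.9	Biopsy	pos	US & CT	4	0	1	1	pos	AdenoCa	Ileocecal junction, spread to mesenteric tissue/jejunum, miliary omental carcinomatosis, metastasis: spleen, uterus, ovary	Weight loss, anemia, umbilical hernia
CRC_6	f	22.8	23.5	Biopsy	n.A	US & CT	3	1	1	1	pos	AdenoCa	Ileocecal junction (resected), tumor recurrence inflicting ovary, distant metastasis to adrenal gland, spine, extensive infiltration of vertebral body L2	st.p. tumor resection, hind limb paresis
CRC_7	m	22.5	23.6	Biopsy	pos	US & CT & FDG-PET	3	1	0	1	pos	Mucinous AdenoCa	Ileocecal junction, metastasis: LN	Hypoalbuminemia
CRC_8	m	18.5	19.6	Biopsy	pos	US & CT & FDG-PET	3	1	0	1	pos	Mucinous AdenoCa	Ileocecal junction, metastasis: LN	Anemia, hypoalbuminemia
CRC_9	f	18.5	18.8	Biopsy	pos	US & CT	3	1	1	1	pos	Mixed (mucinous/AdenoCa/solid)	Ileocecal junction, metastasis: LN, lung, omentum	Weight loss, anemia, hypoproteinemia
CRC_10	f	22.4	22.7	Biopsy	pos	US & CT	4	0	0	1	pos	AdenoCa	Ileocecal junction, local spread to mesentery	Acute gastric bloat, hypochromic-microcytic anemia, hypoalbuminemia, hypoproteinemia, thrombocytosis
CRC_11	f	17.9	19.9	Biopsy	n.A	US & CT	4	1	1	1	pos	AdenoCa	Ileocecal junction, metastasis: lung, liver, uterus, ax. LN, spleen, stomach, adrenal gland, pancreas, urinary bladder, ovary, omentum, bone (rib)	Weight loss, anemia, hypoalbuminemia
CRC_12	f	25.6	26.2	Necropsy	neg	US & CT & contrast-enhanced CT	3	1	0	1	pos	AdenoCa	Ileocecal junction, lymphatic invasion	Abdominal distensions, cecal obstruction, arthritis
CRC_13	m	23.5	23.8	Necropsy	n.A	US & CT	3	0	0	1	pos	AdenoCa	Ileocecal junction	Urinary retention due to chronic bladder atony, weight loss, arthritis, scoliosis, 0.25 x 0.1mm Meningioma
CRC_14	f	23.6	24.9	Biopsy	pos	US & CT & contrast-enhanced CT	2	0	0	1	neg	AdenoCa	Ileocecal junction	Hypoalbuminemia
CRC_15	f	16.5	17.8	Biopsy	pos	US & CT & contrast-enhanced CT	2	0	0	1	pos	AdenoCa	Ileocecal junction	Acute post-surgery complications, hypoalbuminemia
CRC_16	f	18.1	18.2	Necropsy	n.A	n.A	3	0	0	1	pos	AdenoCa	Ileocecal junction	Acute partial cecal obstruction, cachexia
CRC_17	f	21.8	23.6	Necropsy	pos	US & CT	3	0	0	2	pos	Mucinous AdenoCa	Cecocolic junction	Anemia
CRC_18	f	22.1	22.6	Necropsy	pos	US & CT	2	0	0	1	pos	AdenoCa	Ileocecal junction	Anemia
CRC_19	f	24.3	24.8	Biopsy	pos	US & CT & FDG-PET	3	0	0	1	pos	AdenoCa	Ileocecal junction, proximal colon	Anemia
CRC_20	f	20.3	20.8	Necropsy	pos	US & CT	2	0	0	2	pos	AdenoCa	Ileocecal junction	Anemia
CRC_21	f	21.0	21.2	Biopsy	n.A	n.A	3	1	0	3	pos	AdenoCa	Proximal colon, metastasis: mesenteric LN	Cachexia, anemia, esophageal hyperplasia due to chronic gastric reflux
CRC_22	m	17.8	18.4	Necropsy	pos	US & CT & FDG-PET	3	0	0	2	pos	AdenoCa	Proximal colon, small vessel invasion	Anemia
CRC_23	f	18.1	18.7	Necropsy	pos	US & CT	2	0	0	1	pos	AdenoCa	Ileocecal junction	Anemia
CRC_24	f	18.7	n.A	Biopsy	neg	US & CT	3	0	0	3	pos	Mucinous AdenoCa	Ileocecal junction	st.p. tumor resection
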