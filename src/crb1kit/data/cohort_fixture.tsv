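proband_id	alias	diagnosis	subtype	cdna	protein	zygosity	exon	age_of_onset	onset_category	age	bcva_od	bcva_os	reference
Fi25/03_01	CD_1	CD	CD	c.498_506delAATTGATGG	p.Ile167_Gly169del	homo	2	14	adolescence	21	0.8	0.4	[39]
Fi25/04_01	CD_2	CD	CD	c.498_506delAATTGATGG	p.Ile167_Gly169del	het	2	11	late childhood	38	0.3	0.1	[39]
Fi25/04_01	CD_2	CD	CD	c.3299T>C	p.Ile1100Thr	het	9				[40]
Fi25/05_01	CD_3	CD	CD	c.498_506delAATTGATGG	p.Ile167_Gly169del	homo	2	22	adult	32	0.4	0.16	[39]
Fi25/06_01	CD_4	CD	CD	c.498_506delAATTGATGG	p.Ile167_Gly169del	het	2	13	adolescence	35	0.3	0.4	[39]
Fi25/06_01	CD_4	CD	CD	c.3299T>G	p.Ile1100Arg	het	9				[41]
Fi25/07_01	CD_5	CD	extensive CD/inverse RP	c.498_506delAATTGATGG	p.Ile167_Gly169del	het	2	43	adult	51	0.05	0.025	[39]
Fi25/07_01	CD_5	CD	extensive CD/inverse RP	c.1084C>T	p.Gln362Ter	het	5				[42]
Fi25/08_01	CD_6	CD	extensive CD/inverse RP	c.498_506delAATTGATGG	p.Ile167_Gly169del	het	2	14	adolescence	61	0.04	0.04	[39]
Fi25/08_01	CD_6	CD	extensive CD/inverse RP	c.3055_3059dup	p.Met1020IlefsTer4	het	9				[43]
Fi25/09_01	CRD_1	CRD	CRD	c.498_506delAATTGATGG	p.Ile167_Gly169del	het	2	10	late childhood	48	0.1	0.1	[39]
Fi25/09_01	CRD_1	CRD	CRD	c.2843G>A	(Splice) p.Cys948Tyr	het	9				[44]
Fi15/29_01	CRD_2	CRD	PPRPE	c.498_506delAATTGATGG	p.Ile167_Gly169del	het	2	0	infancy	47	LP	HM	[39]
Fi15/29_01	CRD_2	CRD	PPRPE	c.2843G>A	(Splice) p.Cys948Tyr	het	9				[44]
Fi25/20_01	CRD_3	CRD	PPRPE	c.2290C>T	p.Arg764Cys	homo	7	6	late childhood	31	0.5	0.16	[44]
Fi25/20_02	CRD_4	CRD	PPRPE	c.2290C>T	p.Arg764Cys	homo	7	?		36	0.04	0.04	[44]
Fi25/10_01	CRD_5	CRD	CRD	c.498_506delAATTGATGG	p.Ile167_Gly169del	het	2	12	late childhood	58	0.05	0.05	[39]
Fi25/10_01	CRD_5	CRD	CRD	c.1604T>C	p.Leu535Pro	het	6				[45]
Fi25/11_01	CRD_6	CRD	CRD	c.498_506delAATTGATGG	p.Ile167_Gly169del	homo	2	<20	adolescence	64	0.06	0.06	[39]
Fi25/11_01	CRD_6	CRD	CRD	c.1360G>A	p.Gly454Arg	homo	6				[46]
Fi25/12_01	CRD_7	CRD	CRD	c.742T>A	p.Cys248Ser	het	3	17	adolescence	39	0.05	0.05	This study
Fi25/12_01	CRD_7	CRD	CRD	c.4005+1G>A	-	het	11				[47]
Fi25/13_01	CRD_8	CRD	CRD	c.407G>T	p.Cys136Phe	het	2	7	late childhood	57	LP	0.2	This study
Fi25/13_01	CRD_8	CRD	CRD	c.2843G>A	(Splice) p.Cys948Tyr	het	9				[44]
Fi25/14_01	CRD_9	CRD	CRD	c.1760G>A	p.Cys587Tyr	het	6	7	late childhood	67	LP	LP	[6]
Fi25/14_01	CRD_9	CRD	CRD	c.2843G>A	(Splice) p.Cys948Tyr	het	9				[44]
Fi25/15_01	LCA_1	LCA	LCA	c.613_619delATAGGAA	p.Ile205AspfsTer13	het	2	<2	infancy	20	0.04	0.04	[48]
Fi25/15_01	LCA_1	LCA	LCA	c.2290C>T	p.Arg764Cys	het	7				[44]
Fi25/15_02	LCA_2	LCA	LCA	c.613_619delATAGGAA	p.Ile205AspfsTer13	het	2	<2	infancy	15	0.04	0.05	[48]
Fi25/15_02	LCA_2	LCA	LCA	c.2290C>T	p.Arg764Cys	het	7				[44]
Fi15/13_01	LCA_3	LCA	LCA	c.613_619delATAGGAA	p.Ile205AspfsTer13	het	2	<2	infancy	11	0.2	0.1	[48]
Fi15/13_01	LCA_3	LCA	LCA	c.2843G>A	(Splice) p.Cys948Tyr	het	9				[44]
Fi25/21_01	LCA_4	LCA	LCA	c.2843G>A	(Splice) p.Cys948Tyr	homo	9	<2	infancy	23	0.05	0.05	[44]
Fi25/16_01	LCA_5	LCA	LCA	c.613_619delATAGGAA	p.Ile205AspfsTer13	homo	2	<2	infancy	46	0.01	0.04	[48]
Fi25/17_01	LCA_6	LCA	LCA	c.3280C>T	p.Gln1094Ter	homo	9	<2	infancy	16	0.016	0.025	This study
Fi25/18_01	LCA_7	LCA	LCA	c.209delT	p.Met70ArgfsTer17	het	2	<2	infancy	32	HM	HM	This study
Fi25/18_01	LCA_7	LCA	LCA	c.2843G>A	(Splice) p.Cys948Tyr	het	9				[44]
Fi25/19_01	LCA_8	LCA	LCA	c.2843G>A	(Splice) p.Cys948Tyr	het	9	<2	infancy	50	-	-	[44]
Fi25/19_01	LCA_8	LCA	LCA	c.3988G>T	p.Glu1330Ter	het	11				[45]
Fi25/22_02	LCA_9	LCA	LCA	c.2843G>A	(Splice) p.Cys948Tyr	het	9	6 months	infancy	48	HM	LP	[44]
Fi25/22_02	LCA_9	LCA	LCA	c.3749+2_3749+3delTG	-	het	9				[49]
Fi25/22_01	LCA_10	LCA	LCA	c.3749+2_3749+3delTG	-	homo	9	<2	infancy	70	NLP	NLP	[49]
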