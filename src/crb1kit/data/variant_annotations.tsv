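cdna	protein	exon	damaging_count	splice_tokens	novel	maf	reference
c.209delT	p.Met70ArgfsTer17	2	--	--	yes	--	This study
c.407G>T	p.Cys136Phe	2	12D	1G	yes	--	This study
c.498_506delAATTGATGG	p.Ile167_Gly169del	2	--	--	no	--	[39]
c.613_619delATAGGAA	p.Ile205AspfsTer13	2	--	--	no	--	[48]
c.742T>A	p.Cys248Ser	3	14D	2G	yes	0.000002	This study
c.1084C>T	p.Gln362Ter	5	--	--	no	--	[42]
c.1360G>A	p.Gly454Arg	6	14D	2G	no	--	[46]
c.1604T>C	p.Leu535Pro	6	14D	--	no	--	[45]
c.1760G>A	p.Cys587Tyr	6	13D	--	no	--	[6]
c.2290C>T	p.Arg764Cys	7	6D	2G	no	--	[44]
c.2843G>A	p.Cys948Tyr	9	14D	4L	no	--	[44]
c.3055_3059dup	p.Met1020IlefsTer4	9	--	--	no	--	[43]
c.3280C>T	p.Gln1094Ter	9	--	--	yes	--	This study
c.3299T>C	p.Ile1100Thr	9	11D	--	no	--	[40]
c.3299T>G	p.Ile1100Arg	9	14D	--	no	--	[41]
c.3749+2_3749+3delTG	-	9	--	--	no	--	[49]
c.3988G>T	p.Glu1330Ter	11	--	--	no	--	[45]
c.4005+1G>A	-	11	--	--	no	--	[47]
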