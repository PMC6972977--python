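variant_id	gene_region_position	hgvs_c	hgvs_p	exon	domain	variant_type	cadd_score	af_string	af_exac	af_gnomad	novel	evidence	classification_printed
V01	22:43879T>G	c.97T>G	p.(Trp33Gly)	2	HD	Missense	27.20	Not present			1	PM2, PM5, PP3, PP4, A	Likely pathogenic
V02	22:43890_43898del	c.108_116delCGACAAGAG	p.(Asp37_Ser39del)	2	HD	In-frame deletion		Not present			1	PM2, PM4, PP4, A	VUS
V03	22:43904T>C	c.122T>C	p.(Phe41Ser)	2	HD	Missense	28.7	Not present			1	PM6, PM2, PP3, PP4, A	VUS
V04	22:91998del	c.2668delC	p.(Gln890Arg*)	22	TD	Stop-gain		Not present			1	PM2, PVS1, PP4, A	VUS
V05	22:92091G>A	c.2761G>A	p.(Glu921Lys)	22	TD	Missense	33	1:100,000 (ExAC and gnomAD)	0.00001	0.00001	1	PM2, A, B	VUS
V06	22:96106_96126dup	c.3202_3222dupCAGGCCCAGATCGCGGAGCTC	p.(Gln1068_Leu1074dup)	25	TD	In-frame insertion		Not present			1	PM2, PM4, PP4, A, B	VUS
V07	22:98041C>T	c.3584C>T	p.(Ser1195Leu)	27	TD	Missense	23.1	Not present			1	PM2, A	VUS
V08	22:100951A>C	c.4262A>C	p.(Glu1421Ala)	31	TD	Missense	28.5	Not present			1	PM2, PP3, A	VUS
V09	22:100991G>C	c.4302G>C	p.(Gln1434His)	31	TD	Missense	23.5	1:10,000 (ExAC);1:250,000 (gnomAD)	0.0001	0.000004	1	PM2	VUS
V10	22:106186A>G	c.4946A>G	p.(Asp1649Gly)	33	TD	Missense	32	Not present			1	PM2, PP3, PP1, A, B	VUS
V11	22:106272A>G	c.5032A>G	p.(Met1678Val)	33	TD	Missense	18.4	Not present			1	PM2, A	VUS
V12	22:110276del	c.5808delG	p.(Gly1938Alafs*10)	41	NHTD	Frameshift		Not present			1	PM2, #PM4, PM1, PP4, A	Likely pathogenic
V13	22:44002A>G	c.220A>G	p.(Lys74Glu)	2	HD	Missense	23.50	Not present			0	PS4_supporting, PM2, PP4, PP3, A, B	Likely pathogenic
V14	22:44061C>G	c.279C>G	p.(Asn93Lys)	2	HD	Missense	25	Not present			0	PS4, PS3, PM1, PM2, PP4, PP3, A	Pathogenic
V15	22:44065G>A	c.283G>A	p.(Ala95Thr)	2	HD	Missense	29.70	Not present			0	PS4, PM6, PM2, PM1, PP3, A	Pathogenic
V16	22:44069C>T	c.287C>T	p.(Ser96Lys)	2	HD	Missense	32.00	Not present			0	PS4, PM1, PM2, PP4, PP3, A	Pathogenic
V17	22:74704G>C	c.1119G>C	p.(Lys373Asn)	11	HD	Missense	28.8	Not present			0	PS4, PM2, PP4, PP3, A	Likely pathogenic
V18	22:87034C>T	c.2104C>T	p.(Arg702Cys)	17	HD	Missense	35	Not present			0	PS4, PS3, PM2, PP4, PP3, A	Pathogenic
V19	22:87082C>T	c.2152C>T	p.(Arg718Trp)	17	HD	Missense	34	Not present in ExAC; 1:250,000 (gnomAD)		0.000004	0	PS4, PM2, PP1_strong, PP4, PP3, A, B	Pathogenic
V20	22:91361C>T	c.2507C>T	p.(Pro836Lys)	21	TD	Missense	34	Not present			0	PS4, PM2, PP4, PP3, A	Likely pathogenic
V21	22:97950C>T	c.3493C>T	p.(Arg1165Cys)	27	TD	Missense	34	Not present			0	PS4, PM2, PP1_strong, PP4, PP3, A, B	Pathogenic
V22	22:100959G>A	c.4270G>A	p.(Asp1424Asn)	31	TD	Missense	33	Not present			0	PS4, PP1_strong, PM2, PP4, PP3, A	Pathogenic
V23	22:100959G>T	c.4270G>T	p.(Asp1424Tyr)	31	TD	Missense	32	Not present			0	PS4, PP1_strong, PM2, PP4, PP3, A, B	Pathogenic
V24	22:101029A>T	c.4340A>T	p.(Asp1447Val)	31	TD	Missense	31	Not present			0	PS4, PM2, PP4, PP3, A, B	Likely pathogenic
V25	22:108545G>A	c.5521G>A	p.(Glu1841Lys)	39	TD	Missense	34	Not present			0	PS4, PP1_strong, PM2, PP4, PP3, A, B	Pathogenic
V26	22:110238_110247del	c.5770_5779delGGGGACCTGC	p.(Gly1924Argfs*21)	41	NHTD	Frameshift	36	1:50,000 (ExAC); not present in gnomAD	0.00002		0	PS4, #PM4, PM2, PM1, PP4, A	Pathogenic
V27	22:110265C>T	c.5797C>T	p.(Arg1933*)	41	NHTD	Stop-gain	50	1:100,000 (ExAC); 1:250,000 (gnomAD)	0.00001	0.000004	0	PS4, PM2, PM1, PP4, A, B	Pathogenic
V28	22:110268del	c.5800delA	p.(Met1934Trpfs*14)	41	NHTD	Frameshift	34	Not present			0	PS4, #PM4, PM2, PM1, PP4, A	Likely pathogenic
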