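id	mz	adduct	rt_min	mw	formula	name	source_organism	reference_tag
1	127.0755	[M+H]+	2.19	126.0683	C7H10O2	1-Cyclohexenecarboxylic acid	Streptomyces collinus TU 1892	39
2	371.2221	[M-H]-	4.94	372.2294	C23H32O4	Okilactomycin D	Streptomyces scabrisporus F-117187	40
3	554.2564	[M-H]-	9.42	555.2637	C34H37NO6	Viridenomycin	Streptomyces viridochromogenes T-24146 and Streptomyces gannmycicus	41,42
4	213.1483	[M+H]+	2.66	212.14099	C12H20O3	MKN-003B	Streptoverticillium luteoverticillatum 11014 and Streptomyces sp. M02750	43,44
5	467.1361	[M-H]-	1.40	468.1434	C25H24O9	Atramycin A	Streptomyces atratus BY90	45
6	467.1361	[M-H]-	1.40	468.1434	C25H24O9	Antibiotic BE 12406A	Streptomyces sp. BA12406	46,47
7	467.13614	[M-H]-	1.40	468.1434	C25H24O9	Landomycin I (8-D-Olivosyl-landomycin)	Streptomyces cyanogenus S-136	48
8	265.1546	[M+H]+	2.85	264.1473	C14H20N2O3	Bohemamine B	Streptomyces sp. CNQ-583	49
9	265.1546	[M+H]+	2.85	264.1473	C14H20N2O3	Bohemamine C	Streptomyces sp. CNQ-583	49
10	369.1704	[M-H]-	2.49	370.1777	C22H26O5	Furaquinocin C	Streptomyces sp. KO-3988	50
11	273.1817	[M+H]+	2.52	272.1744	C13H24N2O4	Elaiomycin D	Streptomyces sp. HKI0708	51
12	836.3112	[M-H]-	6.24	837.3184	C43H51NO16	Sulfurmycin B	Streptomyces galilaeus OB-111	52,53
13	211.1324	[M+H]+	4.47	210.1251	C12H18O3	Violapyrone A	Streptomyces violascens YIM 100525	54
14	261.1807	[M+H]+	2.13	260.1734	C12H24N2O4	Elaiomycin L	Streptomyces sp. Tü 6399	55
15	217.1428	[M+H]+	2.87	216.1355	C11H20O4	Feigrisolide B	Streptomyces griseus GT 051022	56
16	244.1695	[M+H]+	1.73	243.1623	C16H21NO	Dienomycin C	Streptomyces sp. MC67-C1	57
17	245.1494	[M+H]+	1.81	244.1422	C11H20N2O4	Antibiotic X-1092	Streptomyces sp. X-1092	58
18	400.1764	[M-H]-	6.76	401.1837	C22H27NO6	Tirandamycin D	Streptomyces sp. 307-9	59
19	400.1764	[M-H]-	6.76	401.1837	C22H27NO6	Tirandalydigin	Streptomyces tirandis subsp. umidus AB1006A-9	60
20	421.1038	[M-H]-	5.59	422.1111	C22H18N2O7	Antibiotic FL 120B	Streptomyces chattanoogensis subsp. taitungensis IY2-13	61
21	1135.5238	[M+H]+	0.82	1134.5165	C59H78N2O20	Antibiotic S-583-B	Streptomyces purpurascens S-583	62
22	614.3094	[M+H]+	7.44	613.3021	C30H48NO10P	Phoslactomycin C	Streptomyces nigrescens SC-273	63
23	371.1562	[M-H]-	6.53	372.1635	C15H24N4O7	Clavamycin F	Streptomyces hygroscopicus NRRL 15879	64,65
24	265.1546	[M+H]+	2.93	264.1471	C14H20N2O3	Phenamide	Streptomyces albospinus A19301	66
25	459.14032	[M-H]-	5.45	460.1476	C22H24N2O9	Oxytetracycline	Streptomyces rimosus	67,68
26	655.4051	[M+H]+	2.24	654.3978	C35H58O11	Filipin III	Streptomyces filipinensis	69,70
27	655.4051	[M+H]+	2.24	654.3978	C35H58O11	Filipin IV	Streptomyces filipinensis	69,70
28	486.3055	[M+H]+	3.98	485.2982	C25H43NO8	Novamethymycin	Streptomyces venezuelae	71
29	162.1125	[M+H]+	2.82	161.1052	C7H15NO3	Deoxyvalidamine	Streptomyces hygroscopicus subsp. limoneus	72
30	168.1023	[M+H]+	3.64	167.095	C9H13NO2	L-1,4-Cyclohexadiene-1-alanine	Streptomyces diastatochromogenes var. sakaii	73
31	281.2106	[M+H]+	2.00	280.2033	C17H28O3	PI 201	Streptomyces sp. A7498	74
32	298.1434	[M+H]+	4.43	297.1361	C18H19NO3	Diolmycin A1	Streptomyces sp. WK-2955	75
33	331.2018	[M-H]-	1.80	332.2091	C19H28N2O3	Benzastatine D	Streptomyces nitrosporeus 30643	76
34	331.2018	[M-H]-	1.80	332.2091	C19H28N2O3	Benzastatine E	Streptomyces nitrosporeus 30643	77
35	352.1921	[M-H]-	6.82	353.1994	C22H27NO3	Neocarazostatin B	Streptomyces sp. GP38	78
36	354.1902	[M-H]-	6.93	355.1975	C14H25N7O4	Histargin	Streptomyces roseoviridis MF118-A5	79
37	613.2894	[M+H]+	0.47	612.2821	C36H40N2O7	Aestivophoenin B	Streptomyces purpeofuscus 2887-SVS2	80
38	365.2696	[M+H]+	1.86	364.2624	C22H36O4	Delactonmycin	Streptomyces sp. A92-308902	81
39	369.1704	[M+H]+	2.49	370.1777	C22H26O5	Flaviogeranin	Streptomyces sp. RAC226	82
40	828.3187	[M-H]-	4.87	829.3259	C32H57N5O16P2	Antibiotic EM 2487	Streptomyces sp. Mer-2487	83
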