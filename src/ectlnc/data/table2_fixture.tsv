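seed	seed_lnc_id	ortholog_lnc_id	species	target_id	global_identity_pct	overlap_identity_pct	consistency_flag
1	LTCONS_00008922	CNT2038389	Malus domestica	XM_029094701.1	31	99	-
1	LTCONS_00008922	CNT2092531	Solanum tuberosum	XM_006349290.2	20	100	+
2	LTCONS_00007788	CNT20227177	Theobroma cacao	XM_007012261.2	39	100	-
2	LTCONS_00007788	CNT2072931	Populus trichocarpa	XM_024604078.1	18	100	-
2	LTCONS_00007788	CNT2080641	Oryza nivara	XM_026026114.1	45	100	-
3	LTCONS_00044543	CNT20189851	Prunus persica	XM_020556848.1	13	98	-
4	LTCONS_00026852	CNT20208736	Medicago truncatula	XM_003610710.4	31	98	-
4	LTCONS_00026852	CNT20208735	Medicago truncatula	.	31	98	-
4	LTCONS_00026852	CNT2091126	Solanum tuberosum	XM_006367626	57	94	-
4	LTCONS_00026852	CNT20180321	Arabidopsis thaliana	NM_106318	19	97	-
4	LTCONS_00026852	CNT20229132	Oryza sativa	AK108079	20	97	-
5	LTCONS_00004664	CNT2033313	Glycine max	NM_001360367.2	59	100	-
5	LTCONS_00004664	CNT2047077	Chenopodium quinoa	XM_021860512.1	38	96	-
5	LTCONS_00004664	CNT20237064	Vitis vinifera	XM_019220518.1	46	95	-
6	LTCONS_00016955	CNT2043167	Malus domestica	XM_008383619.2	37	100	+
6	LTCONS_00016955	CNT2043166	Malus domestica	XM_008383620.3	45	100	+
6	LTCONS_00016955	CNT2043165	Malus domestica	XM_008383621.3	19	97	+
6	LTCONS_00016955	CNT2043164	Malus domestica	.	36	100	+
6	LTCONS_00016955	CNT2043163	Malus domestica	.	42	100	+
6	LTCONS_00016955	CNT2039564	Malus domestica	XM_008383620.3	36	100	+
6	LTCONS_00016955	CNT2038026	Malus domestica	XM_008379084.3	42	100	+
6	LTCONS_00016955	CNT2038025	Malus domestica	XM_008379085.3	45	100	+
7	LTCONS_00064414	CNT2035352	Malus domestica	XM_008382323.3	44	96	-
7	LTCONS_00064414	CNT20171807	Brassica oleracea	XM_013748622.1	53	100	-
7	LTCONS_00064414	CNT2044767	Malus domestica	XM_029099752.1	32	100	-
7	LTCONS_00064414	CNT20145755	Brassica napus	XM_013860892.3	44	97	-
7	LTCONS_00064414	CNT208893	Cucumis sativus	XM_004138916.3	69	97	-
7	LTCONS_00064414	CNT208892	Cucumis sativus	.	61	97	-
7	LTCONS_00064414	CNT207653	Cucumis sativus	.	59	94	-
7	LTCONS_00064414	CNT205932	Cucumis sativus	XM_051090445.1	48	98	-
8	LTCONS_00064957	CNT2074390	Populus trichocarpa	XM_006384061.3	50	100	-
8	LTCONS_00064957	CNT2074389	Populus trichocarpa	.	44	100	-
8	LTCONS_00064957	CNT2038576	Malus domestica	XM_008376813.3	25	100	-
9	LTCONS_00005358	CNT20111926	Brassica rapa	XM_009127664.3	62	97	-
9	LTCONS_00005358	CNT20143858	Brassica napus	XM_003757908.1	58	98	-
10	LTCONS_00049549	CNT20116043	Brassica rapa	XM_009134663.3	31	100	-
10	LTCONS_00049549	CNT20149407	Brassica napus	XM_013878762.3	21	91	-
11	LTCONS_00010505	CNT2042500	Malus domestica	XM_029089082.1	35	95	+
11	LTCONS_00010505	CNT2038101	Malus domestica	.	21	98	-
12	LTCONS_00051279	CNT2044449	Malus domestica	XM_008394181.3	23	97	+
12	LTCONS_00051279	CNT2044448	Malus domestica	.	28	97	+
13	LTCONS_00021103	CNT20237770	Vitis vinifera	XM_002267751.4	27	98	-
14	LTCONS_00041093	CNT2037034	Malus domestica	XM_008357492.3	21	100	+
15	LTCONS_00041460	CNT20238040	Vitis vinifera	XM_002281912.3	31	100	-
16	LTCONS_00049579	CNT2043334	Malus domestica	.	.	.	.
17	LTCONS_00063928	CNT2028772	Manihot esculenta	XM_021786738.1	13	96	+
18	LTCONS_00002846	CNT20180106	Arabidopsis lyrata	XM_021024651.1	43	100	-
19	LTCONS_00007220	CNT2075529	Populus trichocarpa	XM_006382832.3	29	100	-
20	LTCONS_00037250	CNT2072920	Populus trichocarpa	XM_006378092.3	61	100	-
21	LTCONS_00050008	CNT2030544	Manihot esculenta	XM_021763170.2	30	100	+
22	LTCONS_00050164	CNT20237038	Vitis vinifera	XM_002279332.4	31	100	-
23	LTCONS_00053896	CNT2072341	Populus trichocarpa	XM_035033563.1	17	96	-
24	LTCONS_00053641	CNT20238707	Vitis vinifera	XM_002262766.4	26	100	-
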