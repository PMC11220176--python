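lnc_id	target_id	global_identity_pct	overlap_identity_pct	consistency_flag
LTCONS_00008922	TEA022935.1	23	97	+
LTCONS_00007788	TEA012272.1	29	99	+
LTCONS_00044543	TEA004681.1	22	97	+
LTCONS_00026852	TEA025907.1	20	99	+
LTCONS_00004664	TEA022107.1	10	100	-
LTCONS_00016955	TEA012518.1	41	99	+
LTCONS_00064414	TEA033352.1	25	88	-
LTCONS_00064957	TEA000254.1	23	91	+
LTCONS_00005358	TEA000289.1	45	98	+
LTCONS_00049549	TEA007641.1	14	96	+
LTCONS_00010505	TEA009846.1	17	99	-
LTCONS_00051279	TEA022308.1	35	96	+
LTCONS_00021103	TEA008317.1	14	98	+
LTCONS_00041093	TEA000506.1	19	92	+
LTCONS_00041460	TEA024759.1	20	100	-
LTCONS_00049579	TEA022706.1	37	100	+
LTCONS_00063928	TEA008207.1	16	85	+
LTCONS_00002846	TEA012270.1	43	97	+
LTCONS_00007220	TEA005414.1	31	91	+
LTCONS_00037250	TEA004050.1	39	100	+
LTCONS_00050008	TEA010642.1	12	99	+
LTCONS_00050164	TEA015820.1	21	89	-
LTCONS_00053896	TEA032488.1	29	98	+
LTCONS_00053641	TEA028539.1	35	99	+
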