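molecule	helix	strand5_start	strand5_end	strand3_start	strand3_end
16S	_length	1500	0	0	0
16S	H1	11	22	31	42
16S	H2	53	64	73	84
16S	H3	95	106	115	126
16S	H4	137	148	157	168
16S	H5	179	190	199	210
16S	H6	221	232	241	252
16S	H7	263	274	283	294
16S	H8	305	316	325	336
16S	H9	347	358	367	378
16S	H10	389	400	409	420
16S	H11	431	442	451	462
16S	H12	473	484	493	504
16S	H13	515	526	535	546
16S	H14	557	568	577	588
16S	H15	599	610	619	630
16S	H16	641	652	661	672
16S	H17	683	694	703	714
16S	H18	725	736	745	756
16S	H19	767	778	787	798
16S	H20	809	820	829	840
16S	H21	851	862	871	882
16S	H22	893	904	913	924
16S	H23	935	946	955	966
16S	H24	977	988	997	1008
16S	H25	1019	1030	1039	1050
16S	H26	1061	1072	1081	1092
16S	H27	1103	1114	1123	1134
16S	H28	1145	1156	1165	1176
16S	H29	1187	1198	1207	1218
16S	H30	1229	1240	1249	1260
16S	H31	1271	1282	1291	1302
16S	H32	1313	1324	1333	1344
16S	H33	1355	1366	1375	1386
16S	H34	1397	1408	1417	1428
16S	H35	1439	1450	1459	1470
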