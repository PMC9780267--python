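index	name	formula	rt_min	cal_mz	obs_mz	ppm_printed	fragments	class_label	reference_confirmed
1	Arillatose B	C22H30O14	8.44	517.1563	517.1569	1.2	137.0223;160.0107;175.0406	oligosaccharide-ester	0
2	Sibiricose A5	C22H30O14	9.44	517.1563	517.1570	1.4	137.0223;160.0173;175.0412;193.0522;341.1177;517.1604	oligosaccharide-ester	1
3	Sibiricose A6	C23H32O15	9.69	547.1668	547.1678	-0.7	137.0538;175.0039;179.0587;190.0279;205.0522;223.0635;341.1117;367.1067;547.1737	oligosaccharide-ester	1
4	Sibiricaxanthone B	C24H26O14	12.35	537.1250	537.1262	2.2	243.0372;297.0414;315.0517;387.0737;406.0900;537.1284	xanthone	1
5	Arillatose A	C34H40O19	12.47	751.2091	751.2126	4.6	397.0579;412.0817;427.1050;443.1373;751.2163	oligosaccharide-ester	0
6	Polygalaxanthone III	C25H28O15	12.79	567.1355	567.1368	2.1	272.0326;297.0417;315.0519;345.0632;357.0637;399.0751;417.0859;447.0953;549.1272;567.1402	xanthone	0
7	7-O-Methylmangiferin	C20H20O11	12.94	435.0933	435.0934	0.1	243.0294;272.0329;300.0280;315.0508;330.0389;345.0613	xanthone	0
8	Tenuifoliside B	C30H36O17	13.35	667.1880	667.1910	4.5	137.0538;175.0040;190.0277;205.0512;223.0617;239.0557;281.0668;461.1321;667.1940	oligosaccharide-ester	1
9	Sibiricaxanthone F	C29H34O16	13.89	637.1774	637.1793	2.9	443.1202;461.1333;637.1857	xanthone	0
10	3,6'-O-Disinapoyl sucrose	C34H42O19	14.82	753.2248	753.2285	4.9	137.0542;175.0043;190.0273;205.0509;223.0617;265.0725;325.0940;367.1047;529.1602;547.1700;753.2323	oligosaccharide-ester	1
11	Arillanin A	C33H40O18	15.14	723.2142	723.2175	4.6	137.0168;175.0402;205.0512;223.0617;265.0727;529.1597;547.1704;723.2205	oligosaccharide-ester	0
12	20-Glc-ginsenoside Rf	C48H82O19	15.28	1007.5421	1007.5453	3.2	475.3791;637.4338;799.4898;961.5449	PPT	0
13	Ginsenoside Rg1	C42H72O14	16.21	845.4893	845.4912	2.2	161.0455;475.3820;637.4375;799.4942	PPT	0
14	Tenuifoliside A	C31H38O17	16.24	1223.3672	1223.3732	4.9	137.0248;179.0358;239.0566;263.0570;281.0675;443.1214;681.2107	oligosaccharide-ester	1
15	Ginsenoside Re	C48H82O18	17.24	991.5472	991.5426	4.6	161.0459;179.0563;475.3813;619.4270;637.4374;765.4870;783.4975;799.4928;945.5529	PPT	1
16	Tenuifoliside C	C35H44O19	17.61	767.2404	767.2431	3.5	137.0526;205.0510;223.0618;265.0725;367.1043;529.1589;767.2496	oligosaccharide-ester	0
17	Reiniose A	C34H42O18	18.14	737.2298	737.2317	2.5	121.0297;147.0457;305.0892;467.1427;615.2023;737.2438	oligosaccharide-ester	0
18	Arillatanoside A	C58H92O28	18.79	1235.5702	1235.5746	4.4	137.0355;337.1152;425.3081;455.3197;469.1594;555.1979;1011.5315;1205.5774;1235.5854	polygala-saponin	0
19	Tenuifoliose A	C62H76O35	20.67	1379.4094	1379.4141	4.6	-	oligosaccharide-ester	0
20	Ginsenoside F3	C41H70O13	21.65	815.4788	815.4812	3.0	161.0462;457.3706;475.3821;619.4274;637.4383;769.4845	PPT	0
21	Ginsenoside Ra1	C58H98O26	22.06	1209.6274	1209.6325	4.2	621.4421;783.4976;945.5551;1077.6001;1209.6475	PPT	0
22	Reinioside A	C42H66O17	22.96	841.4227	841.4268	4.9	161.0463;221.0663;263.0773;425.3071;455.3171;841.4382	polygala-saponin	0
23	Ginsenoside F5	C41H70O13	23.23	815.4788	815.4805	2.1	131.0346;475.3814;637.4372;769.4837;815.4886	PPT	0
24	Ginsenoside Rb1	C54H92O23	23.63	1107.5957	1107.5968	1.0	179.0569;221.0676;621.4431;783.4993;945.5548;1107.6101	PPD	1
25	20(S)-Ginsenoside Rh1	C36H62O9	24.12	683.4365	683.4391	3.8	391.2862;457.3720;475.3812;637.4347	PPT	0
26	Ginsenoside F2	C42H72O13	24.29	829.4944	829.4958	1.6	161.0459;375.2914;459.3847;621.4387;783.4943	PPD	0
27	Ginsenoside Ra2	C58H98O26	24.42	1209.6274	1209.6330	4.7	149.0468;323.0994;621.4400;783.4999;945.5554;1047.5862;1077.5993;1209.6489	PPD	0
28	Ginsenoside Rc	C53H90O22	25.07	1123.5895	1123.5938	3.8	149.0452;621.4389;765.4833;783.4935;915.5386;945.5481;1077.5908	PPD	0
29	20(R)-Ginsenoside Rh1	C36H62O9	25.28	683.4365	683.4387	3.2	161.0482;353.1919;391.2870;475.3789;553.3424;637.4368	PPT	0
30	Ginsenoside Ro	C48H76O19	25.35	955.4908	955.4941	3.4	455.3548;523.3813;569.3880;613.3786;731.4430;793.4433;955.4980	OLE	1
31	Ginsenoside Rb2	C53H90O22	25.73	1123.5895	1123.5946	4.5	783.4956;945.5506;1077.5922	PPD	0
32	Ginsenoside Rb3	C53H90O22	26.11	1123.5895	1123.5942	4.2	783.4957;945.5513;1077.5935	PPD	0
33	Ginsenoside F1	C36H62O9	27.18	683.4365	683.4362	-0.5	161.0483;391.2846;457.3703;475.3816;637.4348	PPT	0
34	Pseudoginsenoside RT1	C47H74O18	28.07	991.5472	991.5510	3.8	161.0464;459.3875;621.4428;765.4891;783.4992;945.5546	OLE	0
35	Ginsenoside Rf	C42H72O14	28.28	845.4893	845.4924	3.7	161.0464;475.3814;637.4360;799.4923	PPT	1
36	Zingibroside R1	C42H66O14	28.88	793.4377	793.4398	2.3	455.3533;569.3864;613.3774;631.3876;793.4420	OLE	0
37	Presenegenin	C30H46O7	30.27	517.3171	517.3177	1.3	351.2704;367.3051;407.2971;411.2858;425.3050;469.2958;487.3024;517.3221	polygala-saponin	0
38	Ginsenoside Rd	C48H82O18	30.89	991.5472	991.5504	3.2	179.0558;221.0667;323.0985;621.4398;783.4962;945.5494	PPD	1
39	Onjisaponin B	C75H112O35	32.18	1571.6911	1571.6945	2.2	-	polygala-saponin	0
40	Tenuifolin	C36H56O12	33.08	679.3699	679.3707	1.2	425.3076;455.3189;679.3759	polygala-saponin	1
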