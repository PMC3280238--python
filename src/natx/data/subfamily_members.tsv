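subfamily	taxon	uniprot	species	rank
1	Tpa7	-	Tityus pachyurus	1
1	To15	-	Tityus obscurus	2
1	Tz2	Q1I165	Tityus zulianus	3
1	TdNa6	C9X4K4	Tityus discrepans	4
2	Ardiscretin	P0C1X7	Tityus discrepans	1
2	TdNa1	C9X4J9	Tityus discrepans	2
2	TdNa2	C9X4K0	Tityus discrepans	3
2	TdNa3	C9X4K1	Tityus discrepans	4
2	TdNa5	C9X4K3	Tityus discrepans	5
2	Bactridin-1	P0CF39	Tityus discrepans	6
2	To5	-	Tityus obscurus	7
3	Tpa4	-	Tityus pachyurus	1
3	To9	-	Tityus obscurus	2
3	To10	-	Tityus obscurus	3
3	To14	-	Tityus obscurus	4
3	TdNa8	C9X4K6	Tityus discrepans	5
3	Ts3	P01496	Tityus serrulatus	6
3	Ts5	P46115	Tityus serrulatus	7
3	Tst3	P0C8X5	Tityus stigmurus	8
3	Tb3	P56608	Tityus bahiensis	9
3	TbTx5	P0C5K8	Tityus bahiensis	10
4	Ts6	P45669	Tityus serrulatus	1
4	TsNTxP	O77463	Tityus serrulatus	2
4	TcoNTxP1	Q5G8A8	Tityus costatus	3
4	TbIT-1	P60275	Tityus bahiensis	4
4	Tf4	P83435	Tityus fasciolatus	5
5	Ts2	P68410	Tityus serrulatus	1
5	Tst2	P68411	Tityus stigmurus	2
5	Tb2	P56609	Tityus bahiensis	3
5	Tb2-II	P60276	Tityus bahiensis	4
5	To12	-	Tityus obscurus	5
6	Tco-gamma	Q5G8B8	Tityus costatus	1
6	Ts1	P15226	Tityus serrulatus	2
6	Tb1	P56611	Tityus bahiensis	3
6	Tst1	P56612	Tityus stigmurus	4
7	Tpa5	-	Tityus pachyurus	1
7	Tpa6	-	Tityus pachyurus	2
7	To6	P84685	Tityus obscurus	3
7	To7	P84688	Tityus obscurus	4
7	TdNa9	C9X4K7	Tityus discrepans	5
7	TdNa10	C9X4K8	Tityus discrepans	6
8	To13	-	Tityus obscurus	1
9	Tpa8	-	Tityus pachyurus	1
10	To8	-	Tityus obscurus	1
11	Tc48a	P60212	Tityus obscurus	1
12	Tpa2	P84631	Tityus pachyurus	1
12	Tc49b	P60214	Tityus obscurus	2
13	Td11	Q1I173	Tityus discrepans	1
13	TdNa7	C9X4J8	Tityus discrepans	2
13	Td3	Q1I177	Tityus discrepans	3
13	Td1	Q1I180	Tityus discrepans	4
13	Td10	Q1I176	Tityus discrepans	5
13	Td6	Q1I167	Tityus discrepans	6
13	Td2	Q1I179	Tityus discrepans	7
13	Td12	Q1I172	Tityus discrepans	8
13	To4	P60215	Tityus obscurus	9
14	Bactridin-2	P0CF37	Tityus discrepans	1
14	Td4	Q1I174	Tityus discrepans	2
14	Td5	Q1I169	Tityus discrepans	3
14	Td8	Q1I163	Tityus discrepans	4
14	Td9	Q1I178	Tityus discrepans	5
14	Td7	Q1I164	Tityus discrepans	6
14	To11	-	Tityus obscurus	7
14	Tc48b/Tc49a	P60213	Tityus obscurus	8
14	Tz1	Q2NME3	Tityus zulianus	9
0	AaHIT4	P21150	Androctonus australis	1
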