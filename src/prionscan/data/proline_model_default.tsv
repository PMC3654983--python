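# max_distance=60	n_pairs=74628
d	observed	expected	lor
1	0.05221900627110468	0.04983777135982931	0.06733544787142559
2	0.04827946615211449	0.0474915573441922	0.02373865779035511
3	0.04742187918743635	0.04525579610477231	0.06745025744997186
4	0.04550570831323364	0.043125287853445965	0.07751344423895637
5	0.04133837165675082	0.04109507759264576	0.008515964383874971
6	0.04156616819424345	0.039160443591349396	0.08601265104436195
7	0.038604813206839256	0.03731688640358463	0.04895211482931802
8	0.03589805434957389	0.03556011840391042	0.013645525173003225
9	0.035509460256204106	0.03388605381553643	0.06751179332972455
10	0.03386128530846331	0.032290799207889034	0.06851358759775227
11	0.031744117489414164	0.03077064444152365	0.04493461155438519
12	0.029251755373318325	0.029322054039323607	-0.003462967033878657
13	0.029224955780672135	0.027941658963917385	0.06478316227725751
14	0.025901806292544353	0.026626248782190515	-0.039796480491081004
15	0.025473012810205285	0.025372764198669	0.005688903607412147
16	0.024106233585249503	0.024178289940408822	-0.004305952128481357
17	0.023181647638955888	0.023040047976843635	0.00883938880529996
18	0.02180146861767701	0.02195539105882195	-0.01014990838508254
19	0.021064479819906737	0.020921796561807142	0.009805547862172368
20	0.02040788980007504	0.019936860618921345	0.03368876175203504
21	0.018893712815565202	0.018998292530188154	-0.007963527787924906
22	0.018531918314841616	0.018103909434971557	0.033710955737589955
23	0.01711153990459345	0.0172516312352206	-0.011763186049003881
24	0.015932357828161013	0.016439475757712582	-0.045204506344895215
25	0.014444980436297368	0.015665554144043463	-0.11702755367686929
26	0.014498579621589751	0.014928066457643786	-0.0421157429413833
27	0.013252398563541835	0.014225297497603229	-0.10220532634791045
28	0.013078201211341588	0.013555612809567887	-0.05172620988295902
29	0.012461810580479177	0.012917454884432546	-0.051808151789274795
30	0.011657822801093424	0.01230933953598733	-0.0784549773874014
31	0.011577424023154847	0.011729852449093876	-0.018870576298847065
32	0.009915849279090958	0.011177645890363165	-0.17280812828482692
33	0.010183845205552875	0.010651435573684823	-0.06476549080901464
34	0.010693037465830519	0.01014999767331799	0.07519232674356006
35	0.009433456611459506	0.009672165977596991	-0.036052501180311926
36	0.008616069035750656	0.009216829176632057	-0.09724070282848533
37	0.008401672294581122	0.008782928277697053	-0.06402550769321738
38	0.008415072090904219	0.00836945414229304	0.007842098057547294
39	0.008039877793857533	0.007975445139159574	0.011608529322977361
40	0.006793696735809616	0.00759998490777524	-0.1617997345083864
41	0.006378303049793643	0.0072422002271459365	-0.18325541854260674
42	0.0062309052902395886	0.006901258984924261	-0.14741778619397977
43	0.006177306104947205	0.006576368242136715	-0.09031326209885919
44	0.005373318325561451	0.006266772389017797	-0.22190928641210028
45	0.005426917510853835	0.005971751387661937	-0.13802112543385694
46	0.005333118936592164	0.005690619097406157	-0.0936061130010189
47	0.004636329527791178	0.0054227216790487184	-0.22603401624676625
48	0.004957924639545479	0.005167436074192433	-0.05971229370600223
49	0.004864126065283808	0.004924168556175941	-0.017699526565387258
50	0.004033338693251862	0.004692353349222852	-0.21833709814025923
51	0.003872541137374712	0.00447145131259723	-0.2074626027381057
52	0.003765342766789945	0.004260948686705123	-0.17839347535668237
53	0.003859141341051616	0.0040603558982259	-0.07332630447411932
54	0.0031891515248968216	0.0038692064214944618	-0.27886505294731145
55	0.0032025513212199175	0.0036870556934861763	-0.20324751861333015
56	0.0030015543763734793	0.0035134800798811002	-0.227190914875298
57	0.0029747547837272875	0.0033480758898028246	-0.17056148092161943
58	0.003135552339604438	0.003190458436940483	-0.02504413802714467
59	0.002626360079326794	0.003040261144870337	-0.2111305238341642
60	0.002666559468296082	0.0028971346944961698	-0.11964725774454722
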