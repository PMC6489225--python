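class	name	gene_id	locus	abiotic	biotic	generative	vegetative
I	HvPUB1	HORVU7Hr1G108540	chr7H:625630612–625,636,687	3	18	14
IIa	HvPUB2	HORVU0Hr1G020210	chrUn:105982242–105,985,875	1	4	4	3
IIa	HvPUB3	HORVU1Hr1G069990	chr1H:487882055–487,884,794	2	5	16	7
IIa	HvPUB4	HORVU2Hr1G068080	chr2H:478112149–478,116,380	2
IIa	HvPUB5	HORVU2Hr1G084670	chr2H:612532269–612,544,059
IIa	HvPUB6	HORVU2Hr1G107270	chr2H:711398163–711,399,326	2	8	3
IIa	HvPUB7	HORVU3Hr1G081300	chr3H:594390155–594,392,901	8	2
IIa	HvPUB9	HORVU3Hr1G113910	chr3H:689573848–689,580,280	8	12	1	1
IIa	HvPUB10	HORVU4Hr1G059610	chr4H:497914351–497,923,545	7	18	10
IIa	HvPUB11	HORVU5Hr1G021270	chr5H:102370756–102,375,777	20	2	22	12
IIa	HvPUB12	HORVU5Hr1G021280	chr5H:102438361–102,442,824	19	2	15	10
IIa	HvPUB13	HORVU5Hr1G059280	chr5H:463207931–463,210,666	6	9	2	4
IIa	HvPUB14	HORVU6Hr1G069010	chr6H:478128962–478,134,602	6	1	4	6
IIa	HvPUB15	HORVU6Hr1G072420	chr6H:503270970–503,276,564	9	6
IIa	HvPUB16	HORVU6Hr1G073280	chr6H:507756329–507,760,902	18	13	9
IIa	HvPUB17	HORVU7Hr1G000780	chr7H:1309283–1,315,775	8	16	14
IIa	HvPUB18	HORVU7Hr1G047920	chr7H:162626044–162,632,315
IIa	HvPUB19	HORVU7Hr1G061800	chr7H:290933777–290,936,462	10	3
IIa	HvPUB20	HORVU7Hr1G121810	chr7H:654539257–654,541,940	3	2
IIa	HvPUB21	HORVU6Hr1G041430	chr6H:228200647–228,211,681	10	8	2	5
IIb	HvPUB22	HORVU2Hr1G067610	chr2H:473427629–473,435,416
IIb	HvPUB24	HORVU3Hr1G083500	chr3H:603823686–603,825,481	2	2	4
IIb	HvPUB25	HORVU5Hr1G029950	chr5H:183287072–183,291,627	19	11	33	2
IIb	HvPUB26	HORVU5Hr1G059910	chr5H:467836849–467,839,703	2	2
IIb	HvPUB28	HORVU7Hr1G039760	chr7H:105941903–105,943,737	5	2
IIb	HvPUB29	HORVU7Hr1G040790	chr7H:111351005–111,354,169	3	1	3	2
IIb	HvPUB57	HORVU6Hr1G066870	chr6H:463530777–463,532,567
IIb	HvPUB60	HORVU6Hr1G095130	chr6H:583093713–583,097,921	9
III	HvPUB31	HORVU4Hr1G070330	chr4H:574972338–574,976,289	2
IV	HvPUB32	HORVU1Hr1G053270	chr1H:393963164–393,967,064	1	3	1
IV	HvPUB33	HORVU2Hr1G013130	chr2H:28662118–28,667,022	6	1
IV	HvPUB34	HORVU4Hr1G017550	chr4H:78074992–78,084,602	2	1	2	1
IV	HvPUB35	HORVU4Hr1G088650	chr4H:640685328–640,696,684	1	1	5
IV	HvPUB36	HORVU5Hr1G060580	chr5H:474627227–474,645,070	6	2
IV	HvPUB37	HORVU5Hr1G077700	chr5H:553639844–553,654,837	1
IV	HvPUB38	HORVU6Hr1G003590	chr6H:8039677–8,048,008	1
IV	HvPUB39	HORVU6Hr1G039290	chr6H:203742583–203,750,519
IV	HvPUB40	HORVU6Hr1G064130	chr6H:433376429–433,381,410	1	2
IV	HvPUB41	HORVU7Hr1G018750	chr7H:25113620–25,118,764	2	1	7
IV	HvPUB42	HORVU7Hr1G086580	chr7H:522444326–522,451,758	14	11	2	2
V	HvPUB8	HORVU3Hr1G089040	chr3H:627083327–627,148,340	1	7	7	14
V	HvPUB23	HORVU4Hr1G064070	chr4H:536981409–536,983,117	1	1	1
V	HvPUB27	HORVU6Hr1G077120	chr6H:528582237–528,584,114	4	2	6
V	HvPUB30	HORVU7Hr1G046920	chr7H:155292351–155,294,342	6	2	6
V	HvPUB43	HORVU2Hr1G104640	chr2H:704314927–704,319,431	1	1
V	HvPUB44	HORVU3Hr1G095960	chr3H:651507615–651,508,824
V	HvPUB45	HORVU5Hr1G005830	chr5H:9430272–9,431,296
V	HvPUB46	HORVU5Hr1G081160	chr5H:563433753–563,438,456
V	HvPUB47	HORVU7Hr1G093780	chr7H:572254844–572,256,019	2
V	HvPUB48	HORVU0Hr1G003810	chrUn:17443362–17,445,805	1	3	8
V	HvPUB49	HORVU1Hr1G074180	chr1H:507187193–507,189,384	2	6
V	HvPUB50	HORVU2Hr1G074130	chr2H:535102978–535,105,576	10	10	1	2
V	HvPUB51	HORVU2Hr1G076470	chr2H:550697966–550,699,310
V	HvPUB52	HORVU2Hr1G105720	chr2H:707375224–707,377,465	2	5
V	HvPUB53	HORVU2Hr1G123130	chr2H:754722899–754,723,432	1
V	HvPUB54	HORVU4Hr1G066070	chr4H:550510764–550,513,664	2	2	11	3
V	HvPUB55	HORVU6Hr1G034250	chr6H:159856080–159,857,826	2
V	HvPUB56	HORVU6Hr1G065480	chr6H:450926585–450,933,083	4	2
V	HvPUB58	HORVU6Hr1G089560	chr6H:570052386–570,053,961	1	9
V	HvPUB59	HORVU6Hr1G089590	chr6H:570107770–570,109,318	1	4
V	HvPUB61	HORVU7Hr1G073100	chr7H:412252306–412,361,703	2	4
VI	HvPUB62	HORVU1Hr1G039050	chr1H:272999682–273,010,309	19	20	5
VI	HvPUB63	HORVU3Hr1G052520	chr3H:381485236–381,496,734	7	2
VI	HvPUB64	HORVU4Hr1G083960	chr4H:627004063–627,010,259	10	1
VII	HvPUB65	HORVU1Hr1G002240	chr1H:4416074–4,418,966	4	11	10
VII	HvPUB66	HORVU7Hr1G076230	chr7H:445084899–445,090,758	7	11	3
X	HvPUB67	HORVU4Hr1G022990	chr4H:122902796–122,907,027	9	8	8
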