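# Synthetic Gompertz-Makeham period life table (a=2.0e-5, b=0.10, c=6e-4),
# calibrated to approximate anchor values of recent US both-sex all-cause mortality.
# Generated by gepnet_cea.lifetable.synth_life_table; NOT a published national table.
age,qx
0,0.0006208413818007408
1,0.0006230521903415331
2,0.00062549550595703
3,0.0006281957803698779
4,0.0006311800366345377
5,0.0006344781395037913
6,0.0006381230942180682
7,0.0006421513767010945
8,0.0006466032984623338
9,0.0006515234098517508
10,0.0006569609456945624
11,0.0006629703177568613
12,0.0006696116589592904
13,0.0006769514247695341
14,0.0006850630577777128
15,0.0006940277220820468
16,0.0007039351148097062
17,0.0007148843628628221
18,0.0007269850138259537
19,0.0007403581309032292
20,0.0007551375027873286
21,0.0007714709804963471
22,0.0007895219544724608
23,0.0008094709866187655
24,0.0008315176134789937
25,0.0008558823384490211
26,0.0008828088327652583
27,0.0009125663670626061
28,0.0009454524975495149
29,0.0009817960333321496
30,0.001021960314156578
31,0.00106634683084883
32,0.001115399224046132
33,0.00116960770045893
34,0.0012295139099059993
35,0.001295716330769081
36,0.001368876216341075
37,0.0014497241598427912
38,0.001539067341689515
39,0.0016377975289498803
40,0.0017468999038938726
41,0.0018674628061273735
42,0.0020006884811014647
43,0.002147904936818712
44,0.0023105790203796772
45,0.0024903308366752697
46,0.0026889496430761994
47,0.002908411366442598
48,0.0031508979022036865
49,0.003418818369677945
50,0.0037148325132071447
51,0.004041876455076254
52,0.004403191023536812
53,0.004802352897482098
54,0.005243308828334903
55,0.005730413219327879
56,0.006268469362361473
57,0.006862774652695469
58,0.0075191701214292195
59,0.008244094644515476
60,0.00904464420418194
61,0.009928636593194762
62,0.010904681963196272
63,0.011982259623911973
64,0.013171801498492952
65,0.014484782629346271
66,0.015933819105682034
67,0.017532773745204566
68,0.019296869803667405
69,0.02124281290231378
70,0.023388921248324368
71,0.02575526406998918
72,0.02836380798758531
73,0.031238570782535446
74,0.0344057816992559
75,0.03789404700196919
76,0.04173451899657776
77,0.0459610660969334
78,0.05061044074492005
79,0.05572244106205948
80,0.06134006099239786
81,0.06750962236706703
82,0.07428088075487527
83,0.08170709513750873
84,0.08984504934358994
85,0.09875501078266913
86,0.10850060934063743
87,0.1191486163547868
88,0.13076860043099348
89,0.14343243358815283
90,0.15721361796137157
91,0.17218640028060794
92,0.18842463887171834
93,0.2060003864201403
94,0.22498215174612513
95,0.2454328060735923
96,0.2674071046106128
97,0.29094880375210874
98,0.3160873690725924
99,0.3428342908131129
100,1.0
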