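# Female calcium turnover fixture, v1: accretion = 150 + 250*exp(-(a-12.5)^2/(2*1.5^2)) mg/day;
# release = (0.15 + 2.35*exp(-a/9.83))/365.25 per day.
age_y,ca_accretion_mg_d,ca_release_frac_d
0.0,150.0,0.006844627
0.25,150.0,0.0066830597
0.5,150.0,0.0065255497
0.75,150.0,0.0063719951
1.0,150.0,0.0062222964
1.25,150.0,0.006076357
1.5,150.0,0.0059340823
1.75,150.0,0.0057953804
2.0,150.0,0.0056601615
2.25,150.0,0.0055283381
2.5,150.0,0.0053998251
2.75,150.0,0.0052745393
3.0,150.0,0.0051523996
3.25,150.000001,0.005033327
3.5,150.000004,0.0049172446
3.75,150.00001,0.0048040771
4.0,150.000027,0.0046937515
4.25,150.000067,0.0045861964
4.5,150.000166,0.0044813421
4.75,150.000399,0.0043791209
5.0,150.000932,0.0042794667
5.25,150.002114,0.0041823149
5.5,150.004666,0.0040876028
5.75,150.010016,0.0039952691
6.0,150.020912,0.003905254
6.25,150.042464,0.0038174993
6.5,150.083866,0.0037319483
6.75,150.161095,0.0036485457
7.0,150.300965,0.0035672374
7.25,150.546873,0.0034879709
7.5,150.96648,0.0034106949
7.75,151.661253,0.0033353595
8.0,152.777249,0.0032619158
8.25,154.515753,0.0031903165
8.5,157.141375,0.0031205151
8.75,160.984233,0.0030524665
9.0,166.432132,0.0029861268
9.25,173.908611,0.002921453
9.5,183.833821,0.0028584032
9.75,196.567616,0.0027969367
10.0,212.338052,0.0027370138
10.25,231.163117,0.0026785956
10.5,252.778073,0.0026216444
10.75,276.583904,0.0025661233
11.0,301.632665,0.0025119964
11.25,326.662069,0.0024592288
11.5,350.184351,0.0024077863
11.75,370.624226,0.0023576355
12.0,386.489867,0.0023087442
12.25,396.551779,0.0022610805
12.5,400.0,0.0022146138
12.75,396.551779,0.002169314
13.0,386.489867,0.0021251517
13.25,370.624226,0.0020820984
13.5,350.184351,0.0020401262
13.75,326.662069,0.001999208
14.0,301.632665,0.0019593174
14.25,276.583904,0.0019204284
14.5,252.778073,0.0018825161
14.75,231.163117,0.0018455557
15.0,212.338052,0.0018095235
15.25,196.567616,0.0017743962
15.5,183.833821,0.0017401509
15.75,173.908611,0.0017067656
16.0,166.432132,0.0016742187
16.25,160.984233,0.0016424891
16.5,157.141375,0.0016115562
16.75,154.515753,0.0015814002
17.0,152.777249,0.0015520014
17.25,151.661253,0.0015233408
17.5,150.96648,0.0014954
17.75,150.546873,0.0014681608
18.0,150.300965,0.0014416056
18.25,150.161095,0.0014157173
18.5,150.083866,0.0013904791
18.75,150.042464,0.0013658746
19.0,150.020912,0.001341888
19.25,150.010016,0.0013185038
19.5,150.004666,0.0012957067
19.75,150.002114,0.0012734822
20.0,150.000932,0.0012518157
20.25,150.000399,0.0012306933
20.5,150.000166,0.0012101014
20.75,150.000067,0.0011900265
21.0,150.000027,0.0011704557
21.25,150.00001,0.0011513764
21.5,150.000004,0.0011327763
21.75,150.000001,0.0011146431
22.0,150.0,0.0010969654
22.25,150.0,0.0010797316
22.5,150.0,0.0010629305
22.75,150.0,0.0010465513
23.0,150.0,0.0010305835
23.25,150.0,0.0010150166
23.5,150.0,0.0009998407
23.75,150.0,0.0009850458
24.0,150.0,0.0009706224
24.25,150.0,0.0009565613
24.5,150.0,0.0009428532
24.75,150.0,0.0009294894
25.0,150.0,0.0009164612
25.25,150.0,0.0009037601
25.5,150.0,0.000891378
25.75,150.0,0.0008793068
26.0,150.0,0.0008675387
26.25,150.0,0.0008560662
26.5,150.0,0.0008448817
26.75,150.0,0.0008339781
27.0,150.0,0.0008233484
27.25,150.0,0.0008129855
27.5,150.0,0.0008028829
27.75,150.0,0.000793034
28.0,150.0,0.0007834323
28.25,150.0,0.0007740719
28.5,150.0,0.0007649464
28.75,150.0,0.0007560501
29.0,150.0,0.0007473773
29.25,150.0,0.0007389222
29.5,150.0,0.0007306794
29.75,150.0,0.0007226436
30.0,150.0,0.0007148096
30.25,150.0,0.0007071724
30.5,150.0,0.0006997269
30.75,150.0,0.0006924684
31.0,150.0,0.0006853921
31.25,150.0,0.0006784936
31.5,150.0,0.0006717683
31.75,150.0,0.0006652119
32.0,150.0,0.0006588201
32.25,150.0,0.0006525888
32.5,150.0,0.000646514
32.75,150.0,0.0006405918
33.0,150.0,0.0006348182
33.25,150.0,0.0006291897
33.5,150.0,0.0006237025
33.75,150.0,0.0006183531
34.0,150.0,0.000613138
34.25,150.0,0.0006080539
34.5,150.0,0.0006030974
34.75,150.0,0.0005982655
35.0,150.0,0.0005935548
35.25,150.0,0.0005889625
35.5,150.0,0.0005844854
35.75,150.0,0.0005801208
36.0,150.0,0.0005758658
36.25,150.0,0.0005717177
36.5,150.0,0.0005676737
36.75,150.0,0.0005637312
37.0,150.0,0.0005598878
37.25,150.0,0.0005561409
37.5,150.0,0.0005524881
37.75,150.0,0.000548927
38.0,150.0,0.0005454553
38.25,150.0,0.0005420708
38.5,150.0,0.0005387713
38.75,150.0,0.0005355547
39.0,150.0,0.0005324188
39.25,150.0,0.0005293617
39.5,150.0,0.0005263813
39.75,150.0,0.0005234758
40.0,150.0,0.0005206432
40.25,150.0,0.0005178818
40.5,150.0,0.0005151897
40.75,150.0,0.0005125653
41.0,150.0,0.0005100067
41.25,150.0,0.0005075124
41.5,150.0,0.0005050807
41.75,150.0,0.0005027101
42.0,150.0,0.000500399
42.25,150.0,0.0004981459
42.5,150.0,0.0004959495
42.75,150.0,0.0004938081
43.0,150.0,0.0004917206
43.25,150.0,0.0004896855
43.5,150.0,0.0004877015
43.75,150.0,0.0004857673
44.0,150.0,0.0004838816
44.25,150.0,0.0004820434
44.5,150.0,0.0004802512
44.75,150.0,0.0004785041
45.0,150.0,0.0004768009
45.25,150.0,0.0004751404
45.5,150.0,0.0004735217
45.75,150.0,0.0004719435
46.0,150.0,0.0004704051
46.25,150.0,0.0004689052
46.5,150.0,0.000467443
46.75,150.0,0.0004660175
47.0,150.0,0.0004646279
47.25,150.0,0.0004632731
47.5,150.0,0.0004619523
47.75,150.0,0.0004606647
48.0,150.0,0.0004594095
48.25,150.0,0.0004581857
48.5,150.0,0.0004569927
48.75,150.0,0.0004558297
49.0,150.0,0.0004546958
49.25,150.0,0.0004535905
49.5,150.0,0.0004525128
49.75,150.0,0.0004514623
50.0,150.0,0.0004504381
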