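case,blast_pct,erythroid_pct,myeloid_pct,monocytic_pct
1,27.5,58.8,5.5,0.4
2,12.3,24.6,5.1,0.3
3,37.5,19.5,2.5,0.1
4,13.0,74.9,7.6,2.5
5,36.1,18.3,17.8,2.7
6,71.6,16.0,12.5,0.0
7,38.6,8.0,3.6,9.3
8,58.9,0.7,19.7,0.0
9,70.2,2.2,21.0,5.5
10,61.8,9.1,8.4,0.0
11,10.2,8.7,43.9,8.6
12,71.7,1.4,3.7,1.0
13,33.9,0.8,37.7,5.1
14,24.6,7.0,36.5,3.5
15,37.7,12.1,20.5,33.5
16,22.1,21.5,5.6,7.6
17,52.0,5.8,10.0,5.1
18,48.9,2.0,20.7,2.7
19,21.7,34.7,5.1,0.4
20,81.4,1.9,3.3,30.8
21,25.0,26.3,3.5,3.7
22,36.5,14.4,26.5,29.3
23,42.7,13.0,19.4,1.6
24,40.2,1.0,14.2,35.4
25,64.1,1.6,20.4,1.4
26,47.5,8.6,4.9,0.3
27,31.8,11.6,1.8,14.2
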