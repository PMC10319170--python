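case,blast_pct,erythroid_pct,myeloid_pct,monocytic_pct
1,0.7,15.3,35.5,15.8
2,1.1,5.1,66.2,3.8
3,0.7,15.1,33.8,2.2
4,4.0,32.3,15.5,3.6
5,1.9,15.4,42.0,13.2
6,0.6,21.3,23.3,7.7
7,0.5,19.7,36.1,2.1
8,0.4,4.7,61.3,3.3
9,0.2,27.9,15.3,2.0
10,8.5,19.0,25.1,1.9
11,2.4,10.4,51.6,0.2
12,2.0,4.9,52.4,1.4
13,1.1,29.8,29.2,7.1
14,1.1,48.0,14.3,0.9
15,6.2,38.7,19.6,2.4
16,1.7,30.2,31.6,2.4
17,3.8,9.4,54.3,3.7
18,0.3,14.0,58.1,2.4
19,0.6,41.9,38.7,1.3
20,28.9,14.7,4.9,2.9
21,1.3,5.4,67.1,3.1
22,1.5,9.7,69.9,2.1
23,4.4,35.0,36.4,2.9
24,1.3,21.5,42.7,1.3
25,0.7,17.0,60.0,3.1
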