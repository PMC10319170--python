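case,blast_pct,erythroid_pct,myeloid_pct,monocytic_pct
1,0.3,9.4,63.6,0.6
2,1.0,19.3,53.6,1.6
3,0.4,16.5,64.6,1.8
4,0.2,19.7,60.7,1.9
5,0.3,17.3,53.2,2.3
6,0.6,13.5,48.6,1.4
7,0.7,21.6,47.6,2.1
8,1.1,18.3,54.6,2.7
9,0.6,13.8,83.8,3.7
10,1.7,13.3,49.1,3.5
11,0.5,12.7,54.0,3.1
12,1.4,16.0,46.1,3.2
13,0.7,27.8,43.0,3.1
14,2.8,12.8,42.9,3.1
15,0.5,21.6,41.6,3.6
16,0.9,12.5,47.7,4.4
17,1.1,13.8,57.1,3.4
18,2.0,10.6,61.1,3.3
19,1.7,15.4,45.7,4.0
20,1.1,15.6,32.2,4.1
21,0.6,9.7,46.0,4.3
22,0.6,18.2,49.8,2.7
23,1.1,11.3,31.8,1.6
24,1.4,14.7,38.1,2.5
25,0.8,20.6,32.5,3.6
26,0.6,21.4,49.4,5.3
27,0.8,28.8,38.2,4.2
28,1.0,17.7,51.3,5.1
29,0.6,17.5,54.0,3.6
30,1.1,13.5,49.5,5.0
31,0.2,28.8,17.3,2.2
32,0.5,11.9,40.4,3.1
33,1.2,25.8,32.5,3.6
34,0.5,11.9,27.8,2.6
35,0.4,16.2,26.6,2.0
36,0.9,11.8,31.7,1.9
37,0.8,18.6,32.1,4.3
38,1.0,29.8,20.1,3.4
39,1.4,13.8,34.0,3.6
40,0.6,30.1,19.6,2.0
41,0.6,19.9,30.8,2.1
42,0.7,13.3,44.8,1.9
43,1.0,22.4,48.1,4.3
44,0.8,16.4,48.9,3.8
45,0.7,17.7,36.9,3.0
46,0.4,15.9,56.5,3.1
47,0.8,15.7,55.7,4.5
48,1.0,7.4,60.2,1.9
49,1.3,11.5,48.3,3.8
50,1.3,19.4,40.1,3.9
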