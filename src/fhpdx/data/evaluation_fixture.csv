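participant,fnta,CSA,CCA,T1S,CL,CranT,CervT,C7S,TK,N,L1,L2,L3,PC,D
1,13,1,1,1,0.1,1,0.1,1,1,2,8,0,0,1,1
2,15,1,1,1,1,1,1,1,1,0,8,0,0,1,1
3,17,1,1,1,1,1,1,1,1,0,8,0,0,1,1
4,17,1,1,1,1,1,1,1,1,0,8,0,0,1,1
5,12,1,1,0.1,0.1,1,0.1,0.1,0.1,5,8,0,0,1,1
6,21,1,1,1,1,1,1,1,1,0,8,0,0,1,1
7,21,1,1,1,1,1,1,1,1,0,8,0,0,1,1
8,11,1,0.1,0.1,0.1,0.1,0.1,0.1,0.1,7,8,0,0,0,1
9,33,2,2,2,2,2,2,2,2,0,0,8,0,2,2
10,31,2,2,2,2,2,2,2,2,0,0,8,0,2,2
11,23,1,1,1,1,1,1,1,1.2,0,8,1,0,1,1
12,17,1,1,1,1,1,1,1,1,7,8,0,0,1,1
13,10,0,0.1,0,0.1,0.1,0.1,0.1,0.1,8,6,0,0,0,0
14,23,1,1,1,1,1,1,1,1.2,0,8,1,0,1,1
15,15,1,1,1,1,1,1,1,1,0,8,0,0,1,1
16,36,2,2,2,2,2,2,2,2,0,0,8,0,2,2
17,23,1,1,1,1,1,1,1,1.2,0,8,1,0,1,1
18,29,2,2,2,2,2,2,2,2,0,0,8,0,2,2
19,6,0,0,0,0,0,0,0,0,8,0,0,0,0,0
20,16,1,1,1,1,1,1,1,1,0,8,0,0,1,1
21,13,1,1,1,0.1,1,0.1,1,1,2,8,0,0,1,1
22,4,0,0,0,0,0,0,0,0,8,0,0,0,0,0
23,17,1,1,1,1,1,1,1,1,0,8,0,0,1,1
24,1,0,0,0,0,0,0,0,0,8,0,0,0,0,0
25,25,1,1.2,1.2,1.2,1.2,1.2,1.2,1.2,0,8,7,0,2,1
26,27,2,2,2,1.2,1.2,2,2,1.2,0,3,8,0,2,2
27,31,2,2,2,2,2,2,2,2,0,0,8,0,2,2
28,12,1,1,0.1,0.1,1,0.1,0.1,0.1,5,8,0,0,1,1
29,52,3,3,3,3,3,3,3,3,0,0,0,8,3,3
30,13,1,1,1,0.1,1,0.1,1,1,2,8,0,0,1,1
31,20,1,1,1,1,1,1,1,1,0,8,0,0,1,1
32,7,0,0,0,0.1,0,0,0,0,8,1,0,0,0,0
33,15,1,1,1,1,1,1,1,1,0,8,0,0,1,1
34,19,1,1,1,1,1,1,1,1,0,8,0,0,1,1
35,9,0,0,0,0.1,0,0.1,0,0.1,8,3,0,0,0,0
36,13,1,1,1,0.1,1,0.1,1,1,2,8,0,0,1,1
37,19,1,1,1,1,1,1,1,1,0,8,0,0,1,1
38,21,1,1,1,1,1,1,1,1,0,8,0,0,1,1
39,21,1,1,1,1,1,1,1,1,0,8,0,0,1,1
40,22,1,1,1,1,1,1,1,1.2,0,8,1,0,1,1
41,10,0,0.1,0,0.1,0.1,0.1,0.1,0.1,8,6,0,0,0,0
42,62,3,3,3,3,3,3,3,3,0,0,0,8,3,3
43,10,0,0.1,0,0.1,0.1,0.1,0.1,0.1,8,6,0,0,0,0
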