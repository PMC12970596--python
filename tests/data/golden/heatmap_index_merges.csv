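left,right,height,count
36,41,0.02289920235,2
15,24,0.02945496196,2
38,42,0.03342344123,3
19,40,0.03971763673,2
4,7,0.04218975023,2
34,44,0.05195675694,4
18,45,0.06890685946,3
23,31,0.07198098491,2
46,47,0.07659595725,6
35,39,0.09805592678,2
28,43,0.1081095878,3
14,27,0.1263711647,2
5,12,0.1567812759,2
48,51,0.1906105354,5
0,53,0.2260526117,3
6,52,0.2326340807,4
50,55,0.2339456991,11
9,20,0.2852707105,2
33,54,0.3382214617,3
32,37,0.3740868902,2
49,57,0.4170642004,6
56,60,0.5170057846,6
8,25,0.5861687233,2
2,59,0.6042137211,3
10,30,0.641993153,2
11,29,0.6454142029,2
58,62,0.6872478373,17
17,61,0.9108790796,3
1,63,0.9232206046,7
16,68,1.19514631,18
3,65,1.35976704,4
13,26,1.67931694,2
64,66,1.702197028,4
69,70,1.882723369,10
21,71,1.899741595,19
22,72,2.245482686,5
67,77,3.161080924,7
73,75,3.628121683,12
74,76,3.771193381,23
78,79,4.395984817,19
80,81,4.471554575,42
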