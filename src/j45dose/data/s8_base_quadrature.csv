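bin_index,level,mu,eta,beta_sign,weight,is_starting
0,1,-0.30860679612398356,0.95118970000000003,0,0,1
1,1,-0.21821789999999999,0.95118970000000003,1,0.030246928024692799,0
2,1,0.21821789999999999,0.95118970000000003,1,0.030246928024692799,0
3,2,-0.61721339024875344,0.78679580000000005,0,0,1
4,2,-0.57735029999999998,0.78679580000000005,1,0.022685177268517723,0
5,2,-0.21821789999999999,0.78679580000000005,1,0.022685177268517723,0
6,2,0.21821789999999999,0.78679580000000005,1,0.022685177268517723,0
7,2,0.57735029999999998,0.78679580000000005,1,0.022685177268517723,0
8,3,-0.81649655914150066,0.57735029999999998,0,0,1
9,3,-0.78679580000000005,0.57735029999999998,1,0.022685177268517723,0
10,3,-0.57735029999999998,0.57735029999999998,1,0.023148152314815228,0
11,3,-0.21821789999999999,0.57735029999999998,1,0.022685177268517723,0
12,3,0.21821789999999999,0.57735029999999998,1,0.022685177268517723,0
13,3,0.57735029999999998,0.57735029999999998,1,0.023148152314815228,0
14,3,0.78679580000000005,0.57735029999999998,1,0.022685177268517723,0
15,4,-0.97590007076523466,0.21821789999999999,0,0,1
16,4,-0.95118970000000003,0.21821789999999999,1,0.030246928024692799,0
17,4,-0.78679580000000005,0.21821789999999999,1,0.022685177268517723,0
18,4,-0.57735029999999998,0.21821789999999999,1,0.022685177268517723,0
19,4,-0.21821789999999999,0.21821789999999999,1,0.030246928024692799,0
20,4,0.21821789999999999,0.21821789999999999,1,0.030246928024692799,0
21,4,0.57735029999999998,0.21821789999999999,1,0.022685177268517723,0
22,4,0.78679580000000005,0.21821789999999999,1,0.022685177268517723,0
23,4,0.95118970000000003,0.21821789999999999,1,0.030246928024692799,0
24,5,-0.97590007076523466,-0.21821789999999999,0,0,1
25,5,-0.95118970000000003,-0.21821789999999999,1,0.030246928024692799,0
26,5,-0.78679580000000005,-0.21821789999999999,1,0.022685177268517723,0
27,5,-0.57735029999999998,-0.21821789999999999,1,0.022685177268517723,0
28,5,-0.21821789999999999,-0.21821789999999999,1,0.030246928024692799,0
29,5,0.21821789999999999,-0.21821789999999999,1,0.030246928024692799,0
30,5,0.57735029999999998,-0.21821789999999999,1,0.022685177268517723,0
31,5,0.78679580000000005,-0.21821789999999999,1,0.022685177268517723,0
32,5,0.95118970000000003,-0.21821789999999999,1,0.030246928024692799,0
33,6,-0.81649655914150066,-0.57735029999999998,0,0,1
34,6,-0.78679580000000005,-0.57735029999999998,1,0.022685177268517723,0
35,6,-0.57735029999999998,-0.57735029999999998,1,0.023148152314815228,0
36,6,-0.21821789999999999,-0.57735029999999998,1,0.022685177268517723,0
37,6,0.21821789999999999,-0.57735029999999998,1,0.022685177268517723,0
38,6,0.57735029999999998,-0.57735029999999998,1,0.023148152314815228,0
39,6,0.78679580000000005,-0.57735029999999998,1,0.022685177268517723,0
40,7,-0.61721339024875344,-0.78679580000000005,0,0,1
41,7,-0.57735029999999998,-0.78679580000000005,1,0.022685177268517723,0
42,7,-0.21821789999999999,-0.78679580000000005,1,0.022685177268517723,0
43,7,0.21821789999999999,-0.78679580000000005,1,0.022685177268517723,0
44,7,0.57735029999999998,-0.78679580000000005,1,0.022685177268517723,0
45,8,-0.30860679612398356,-0.95118970000000003,0,0,1
46,8,-0.21821789999999999,-0.95118970000000003,1,0.030246928024692799,0
47,8,0.21821789999999999,-0.95118970000000003,1,0.030246928024692799,0
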