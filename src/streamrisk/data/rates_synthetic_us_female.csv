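age,bc_incidence_per_100k,competing_survival
0,0.0,0.999965
1,0.0,0.999962
2,0.0,0.999958
3,0.0,0.999954
4,0.0,0.99995
5,0.0,0.999945
6,0.0,0.99994
7,0.0,0.999934
8,0.0,0.999928
9,0.0,0.999921
10,0.0,0.999914
11,0.0,0.999906
12,0.0,0.999897
13,0.0,0.999887
14,0.0,0.999877
15,0.0,0.999865
16,0.0,0.999852
17,0.0,0.999838
18,0.0,0.999823
19,0.0,0.999807
20,5.59,0.999788
21,6.33,0.999768
22,7.16,0.999747
23,8.09,0.999723
24,9.15,0.999697
25,10.34,0.999668
26,11.68,0.999637
27,13.19,0.999603
28,14.89,0.999565
29,16.8,0.999524
30,18.94,0.999479
31,21.34,0.99943
32,24.03,0.999377
33,27.04,0.999318
34,30.4,0.999254
35,34.14,0.999184
36,38.29,0.999107
37,42.91,0.999023
38,48.01,0.998931
39,53.64,0.99883
40,59.83,0.99872
41,66.62,0.998599
42,74.03,0.998468
43,82.09,0.998323
44,90.82,0.998166
45,100.22,0.997993
46,110.29,0.997804
47,121.02,0.997598
48,132.4,0.997372
49,144.37,0.997125
50,156.89,0.996854
51,169.89,0.996559
52,183.3,0.996235
53,197.02,0.995881
54,210.96,0.995494
55,225.0,0.995071
56,239.04,0.994608
57,252.98,0.994102
58,266.7,0.993548
59,280.11,0.992943
60,293.11,0.992281
61,305.63,0.991557
62,317.6,0.990765
63,328.98,0.9899
64,339.71,0.988954
65,349.78,0.98792
66,359.18,0.98679
67,367.91,0.985555
68,375.97,0.984206
69,383.38,0.982731
70,390.17,0.98112
71,396.36,0.979361
72,401.99,0.977439
73,407.09,0.975341
74,411.71,0.973051
75,415.86,0.97055
76,419.6,0.967822
77,422.96,0.964846
78,425.97,0.961599
79,428.66,0.95806
80,431.06,0.954202
81,433.2,0.949998
82,435.11,0.94542
83,436.81,0.940436
84,438.32,0.935013
85,439.66,0.929115
86,440.85,0.922704
87,441.91,0.91574
88,442.84,0.908181
89,443.67,0.899981
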