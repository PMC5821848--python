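k,mean_silhouette,explained_dissimilarity
2,0.410,0.384
3,0.290,0.707
4,0.314,0.840
5,0.298,0.876
6,0.313,0.909
7,0.336,0.925
8,0.334,0.937
9,0.346,0.942
10,0.320,0.953
11,0.319,0.960
12,0.321,0.966
13,0.335,0.968
14,0.355,0.971
15,0.340,0.975
16,0.340,0.979
17,0.344,0.980
18,0.348,0.981
19,0.337,0.983
20,0.354,0.984
21,0.342,0.985
22,0.350,0.986
23,0.326,0.987
24,0.346,0.988
25,0.333,0.989
26,0.348,0.990
27,0.351,0.990
28,0.355,0.991
29,0.359,0.991
30,0.363,0.992
31,0.369,0.992
32,0.370,0.993
33,0.378,0.993
34,0.371,0.993
35,0.374,0.994
36,0.376,0.994
37,0.363,0.994
38,0.357,0.994
39,0.352,0.994
40,0.346,0.994
41,0.352,0.995
42,0.356,0.995
43,0.361,0.995
44,0.362,0.995
45,0.364,0.996
46,0.360,0.996
47,0.363,0.996
48,0.365,0.996
49,0.364,0.996
50,0.366,0.996
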