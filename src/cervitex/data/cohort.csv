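patient_id,gender,age,h_mean,angle_1,angle_2,area,contrast,homogeneity,correlation,energy,input_class,gep_h,predicted_class
1,male,29,3.5,72.42,41.35,1103,0.297,0.914,0.907,0.306,0,0.006,0
2,male,30,1.5,52.06,60.84,896,0.765,0.836,0.770,0.230,0,0.028,0
3,male,32,9.0,79.65,71.05,1012,1.293,0.854,0.797,0.407,0,0.001,0
4,male,35,3.5,62.86,36.87,986,0.451,0.913,0.758,0.392,0,0.004,0
5,male,35,7.5,59.96,59.1,1279,0.577,0.881,0.879,0.382,0,0.001,0
6,male,38,9.0,90.01,50.04,1070,0.550,0.899,0.846,0.430,0,0.001,0
7,male,41,6.0,87.07,47.67,1009,1.300,0.839,0.653,0.399,0,0.001,0
8,male,43,3.5,65.4,47.12,993,0.168,0.945,0.935,0.358,0,0.028,0
9,male,46,9.0,53.61,56.95,941,0.499,0.930,0.706,0.681,0,0.001,0
10,male,51,0.5,70.13,46.61,939,0.376,0.899,0.780,0.386,0,0.001,0
11,male,54,0.5,75.32,40.08,966,0.188,0.962,0.849,0.760,0,0.001,0
12,male,58,0.8,38.29,38.81,1123,0.310,0.941,0.857,0.602,0,0.001,0
13,female,25,9.0,89.08,68.77,1170,0.679,0.875,0.688,0.290,0,0.001,0
14,female,27,9.0,86.97,52.87,1305,0.300,0.930,0.810,0.412,0,0.001,0
15,female,28,9.0,77.25,74.22,1005,1.128,0.809,0.643,0.194,0,0.001,0
16,female,28,8.0,88.87,71.37,414,1.926,0.791,0.609,0.158,0,0.001,0
17,female,28,9.0,93.01,69.41,921,0.395,0.912,0.754,0.473,0,0.001,0
18,female,29,9.0,93.61,55.29,1105,0.675,0.886,0.683,0.373,0,0.001,0
19,female,30,7.0,101.89,68.45,917,0.149,0.951,0.934,0.494,0,0.004,0
20,female,31,7.0,84.22,53.13,1260,0.147,0.952,0.941,0.451,0,0.003,0
21,female,32,6.0,89.95,62.34,1094,0.595,0.893,0.739,0.350,0,0.001,0
22,female,32,7.5,99.41,54.11,988,0.364,0.904,0.775,0.357,0,0.001,0
23,female,32,9.0,94.01,58.35,1111,0.566,0.902,0.770,0.352,0,0.001,0
24,female,33,5.6,91.76,58.65,1010,0.148,0.954,0.944,0.440,0,0.016,0
25,female,35,5.5,98.58,62.61,1064,0.817,0.866,0.701,0.272,0,0.001,0
26,female,35,5.5,82.75,49.65,1084,0.503,0.887,0.761,0.278,0,0.001,0
27,female,35,7.0,90.62,51.84,1116,0.358,0.902,0.794,0.333,0,0.001,0
28,female,36,4.5,89.32,62.01,1159,0.247,0.950,0.789,0.593,0,0.114,0
29,female,37,5.5,89.31,60.28,1023,0.123,0.953,0.931,0.511,0,0.093,0
30,female,42,1.5,85.57,42.02,1080,0.533,0.889,0.753,0.385,0,0.001,0
31,female,42,5.5,76.91,69.09,1057,0.605,0.872,0.778,0.307,0,0.001,0
32,female,46,0.8,77.76,48.61,848,0.418,0.923,0.826,0.397,0,0.001,0
33,female,48,1.5,90.26,46.14,1050,0.158,0.946,0.939,0.419,0,0.001,0
34,female,50,7.0,80.89,50.87,987,0.156,0.948,0.939,0.417,0,0.002,0
35,male,37,4.5,57.05,56.14,1065,0.142,0.953,0.931,0.470,1,0.694,1
36,male,39,2.5,60.48,46.15,1044,0.170,0.948,0.940,0.395,1,1.000,1
37,male,41,3.0,67.85,50.57,912,0.146,0.952,0.937,0.459,1,1.000,1
38,male,45,1.5,85.49,58.04,1143,0.265,0.945,0.846,0.661,1,1.000,1
39,female,24,2.5,79.82,50.52,1055,0.822,0.868,0.711,0.432,1,0.691,1
40,female,27,4.0,79.57,48.55,269,2.881,0.751,0.505,0.170,1,1.000,1
41,female,30,1.5,64.12,51.31,888,0.837,0.839,0.652,0.237,1,0.940,1
42,female,36,2.0,79.64,54.06,1067,0.472,0.898,0.764,0.497,1,1.000,1
43,male,35,7.0,77.17,52.06,1075,0.080,0.977,0.946,0.727,0,0.994,1
44,male,48,2.5,90.47,64.04,985,0.182,0.937,0.931,0.365,0,1.000,1
45,male,50,1.5,82.09,34.24,789,1.321,0.845,0.669,0.337,0,1.000,1
46,female,32,1.5,77.08,40.72,961,0.423,0.910,0.771,0.385,0,1.000,1
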