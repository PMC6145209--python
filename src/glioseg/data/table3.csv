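patient_id,area_t2,area_flair,area_pmap,di_tp,di_fp,di_tf
1,15.07,18.04,12.35,0.609,0.481,0.672
2,7.18,12.67,8.89,0.411,0.304,0.457
3,13.95,14.43,13.99,0.296,0.340,0.187
4,12.32,14.23,17.06,0.472,0.506,0.598
5,7.24,14.98,10.12,0.577,0.472,0.429
6,32.52,34.58,17.98,0.572,0.583,0.393
7,35.97,33.19,24.19,0.476,0.591,0.367
8,18.02,19.27,22.15,0.258,0.321,0.225
9,6.84,8.85,3.95,0.329,0.379,0.347
10,5.16,6.10,2.95,0.589,0.640,0.228
11,23.05,25.87,21.76,0.266,0.215,0.128
12,11.84,13.67,7.50,0.508,0.575,0.395
13,13.00,13.61,10.02,0.457,0.686,0.453
14,4.75,7.97,2.98,0.480,0.761,0.569
15,8.21,9.52,3.14,0.794,0.772,0.731
16,29.09,23.94,18.84,0.433,0.230,0.336
17,8.39,8.52,9.85,0.300,0.254,0.240
18,12.25,12.01,9.12,0.315,0.214,0.178
19,14.85,9.59,7.32,0.495,0.615,0.658
20,6.12,6.18,4.72,0.512,0.248,0.123
21,3.08,2.52,4.26,0.375,0.411,0.261
22,5.19,7.35,4.45,0.482,0.522,0.714
23,9.62,9.88,8.14,0.430,0.472,0.430
24,8.59,11.05,12.5,0.721,0.239,0.689
25,10.13,12.25,6.62,0.549,0.738,0.776
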