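compound_id,ec50_molpct,hill_n,kini_pct_per_s,alogps,rt_min,r4,r5,r6_class,ec50_imputed
1,0.00719,1.19,0.952,3.08,10.4,,,,false
2,0.00613,1.23,1.41,3.74,11,,,,false
3,0.00699,1.25,1.24,4.17,11.6,,,,false
4,0.00779,1.32,1.17,4.63,12.2,,,,false
5,0.0104,1.29,1.02,4.72,11.9,,,,false
6,0.00951,1.25,1.13,5.02,12.7,,,,false
7,0.288,0.965,0.0231,7.11,14.5,,,,false
8,0.0688,1.42,0.229,2.58,8.8,,,,false
9,0.0197,1.29,0.638,2.86,9.8,,,,false
10,0.0134,1.28,0.786,3.37,10.5,,,,false
11,0.0231,1.31,0.470,3.76,11,,,,false
12,0.0260,1.29,0.494,3.2,10.4,,,,false
13,0.0208,1.18,0.474,2.92,9.6,,,,false
14,0.0155,1.27,0.661,3.49,10.3,,,,false
15,0.0236,1.37,0.444,3.62,10.5,,,,false
16,0.0221,1.29,0.510,3.76,10.8,,,,false
17,0.0167,1.48,0.830,2.68,9,,,,false
18,0.0494,1.59,0.314,2.11,8.2,,,,false
19,0.197,0.853,0.0919,1.88,,,NH-CH2-Ph,,false
20,0.346,1.30,0.0368,1.03,7,,,,false
21,0.0921,1.08,0.215,1.55,7.7,,,,false
22,0.0274,1.03,0.517,2.03,8.5,,,,false
23,0.0116,0.860,0.743,2.46,9.3,,,,false
24,0.00648,1.18,1.46,2.99,10.2,,,,false
25,0.005,1.19,1.50,3.52,10.9,,,,false
26,0.00451,1.51,1.52,4.02,11.5,,,,false
27,0.00312,1.07,2.63,4.79,12.1,,,,false
28,0.0038,1.10,1.63,5.1,12.6,,,,false
29,0.0053,1.33,1.54,5.36,13.1,,,,false
30,0.00731,1.15,1.09,6.14,13.8,,,,false
31,0.0113,1.20,0.941,2.24,9.2,,,,false
32,0.00668,1.05,1.01,2.84,10,,,,false
33,0.0977,0.963,0.224,1.5,,,,,false
34,0.0157,1.32,0.744,4.4,11.5,,,,false
35,0.0116,1.20,0.708,5.94,13.1,,,,false
36,0.0123,0.857,0.321,6.46,,,,,false
37,0.0133,1.45,0.600,4.38,11.6,,,,false
38,0.00878,1.43,1.69,3.3,11.3,,NH-py,,false
39,0.0196,1.14,0.605,3.62,10.7,,,,false
40,0.00968,1.74,1.16,4.49,11.9,,,,false
41,0.00517,1.15,1.04,6.07,,,,,false
42,0.0204,0.929,0.420,6.42,13.9,,,,false
43,0.0616,,0.186,7.14,10.4,,,,true
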