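age_band,inc_t2d,inc_cancer,inc_stroke,inc_chd,mort_cvd,mort_allcause,cfr_chd,cfr_stroke
30-34,0.0016,0.0011,0.0003,0.0001,0.00002,0.00046,0.0877,0.2346
35-39,0.0018,0.0016,0.0005,0.0003,0.00005,0.00059,0.0877,0.2346
40-44,0.0031,0.0022,0.0010,0.0006,0.0001,0.00082,0.0877,0.2346
45-49,0.0050,0.0035,0.0017,0.0010,0.0002,0.00136,0.0877,0.2346
50-54,0.0076,0.0058,0.0025,0.0018,0.0004,0.00231,0.0877,0.2346
55-59,0.0098,0.0087,0.0033,0.0029,0.0007,0.00384,0.1155,0.2328
60-64,0.0106,0.0134,0.0044,0.0046,0.0011,0.00610,0.1155,0.2328
65-69,0.0105,0.0190,0.0056,0.0069,0.0020,0.01052,0.2107,0.2347
70+,0.0121,0.0252,0.0070,0.0102,0.0036,0.01742,0.2107,0.2347
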