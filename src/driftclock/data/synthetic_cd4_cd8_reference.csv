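cpg_id,CD4,CD8
cgref000,0.8649,0.98
cgref001,0.1983,0.02
cgref002,0.8006,0.98
cgref003,0.8449,0.5449
cgref004,0.4176,0.7466
cgref005,0.1527,0.02
cgref006,0.8858,0.98
cgref007,0.8259,0.5877
cgref008,0.6355,0.7984
cgref009,0.3857,0.1858
cgref010,0.2865,0.4565
cgref011,0.5516,0.3734
cgref012,0.1428,0.3922
cgref013,0.5292,0.1817
cgref014,0.2201,0.4369
cgref015,0.4797,0.2137
cgref016,0.4935,0.6929
cgref017,0.7344,0.4304
cgref018,0.2167,0.3702
cgref019,0.4409,0.1917
cgref020,0.6273,0.8654
cgref021,0.1209,0.02
cgref022,0.2122,0.3878
cgref023,0.4596,0.1181
cgref024,0.8617,0.98
cgref025,0.3546,0.0696
cgref026,0.8281,0.98
cgref027,0.3255,0.02
cgref028,0.1666,0.5085
cgref029,0.4463,0.1458
cgref030,0.7793,0.9407
cgref031,0.7849,0.6198
cgref032,0.8152,0.9774
cgref033,0.8312,0.5849
cgref034,0.5384,0.7642
cgref035,0.2583,0.0842
cgref036,0.2417,0.5898
cgref037,0.3371,0.1442
cgref038,0.2496,0.4561
cgref039,0.4761,0.2585
cgref040,0.6609,0.9759
cgref041,0.8157,0.564
cgref042,0.6117,0.8548
cgref043,0.1876,0.02
cgref044,0.8738,0.98
cgref045,0.8288,0.5223
cgref046,0.2191,0.443
cgref047,0.332,0.1379
cgref048,0.2278,0.382
cgref049,0.3744,0.2073
cgref050,0.1206,0.4238
cgref051,0.4808,0.1706
cgref052,0.882,0.98
cgref053,0.3162,0.1525
cgref054,0.2478,0.5963
cgref055,0.8707,0.5433
cgref056,0.3836,0.6174
cgref057,0.2895,0.1311
cgref058,0.4164,0.6921
cgref059,0.2549,0.02
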