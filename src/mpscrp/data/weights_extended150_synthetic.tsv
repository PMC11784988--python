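cpg_id	weight
cg_m0000001	-0.3573
cg_m0000002	-0.0937
cg_m0000003	-0.1214
cg_m0000004	0.0541
cg_m0000005	-0.2278
cg_m0000006	-0.0736
cg_e0000001	0.0225
cg_e0000002	0.0180
cg_e0000003	0.0395
cg_e0000004	0.0335
cg_e0000005	0.0344
cg_e0000006	-0.0156
cg_e0000007	-0.0288
cg_e0000008	0.0230
cg_e0000009	0.0267
cg_e0000010	0.0076
cg_e0000011	-0.0519
cg_e0000012	0.0296
cg_e0000013	-0.0184
cg_e0000014	-0.0338
cg_e0000015	0.0107
cg_e0000016	-0.0134
cg_e0000017	0.0361
cg_e0000018	0.0195
cg_e0000019	-0.0402
cg_e0000020	0.0320
cg_e0000021	0.0157
cg_e0000022	0.0035
cg_e0000023	-0.0113
cg_e0000024	0.0428
cg_e0000025	0.0203
cg_e0000026	-0.0221
cg_e0000027	-0.0265
cg_e0000028	-0.0501
cg_e0000029	-0.0190
cg_e0000030	0.0323
cg_e0000031	-0.0245
cg_e0000032	0.0611
cg_e0000033	0.0075
cg_e0000034	0.0077
cg_e0000035	0.0184
cg_e0000036	-0.0084
cg_e0000037	-0.0342
cg_e0000038	0.0102
cg_e0000039	0.0071
cg_e0000040	-0.0491
cg_e0000041	-0.0457
cg_e0000042	0.0142
cg_e0000043	-0.0202
cg_e0000044	0.0096
cg_e0000045	-0.0375
cg_e0000046	0.0351
cg_e0000047	-0.0094
cg_e0000048	-0.0132
cg_e0000049	0.0553
cg_e0000050	0.0025
cg_e0000051	0.0127
cg_e0000052	-0.0194
cg_e0000053	-0.0245
cg_e0000054	0.0423
cg_e0000055	0.0121
cg_e0000056	0.0318
cg_e0000057	0.0154
cg_e0000058	-0.0116
cg_e0000059	-0.0253
cg_e0000060	0.0182
cg_e0000061	-0.0189
cg_e0000062	0.0207
cg_e0000063	0.0469
cg_e0000064	0.0422
cg_e0000065	-0.0251
cg_e0000066	-0.0107
cg_e0000067	-0.0162
cg_e0000068	-0.0385
cg_e0000069	0.0213
cg_e0000070	0.0053
cg_e0000071	0.0267
cg_e0000072	0.0047
cg_e0000073	0.0554
cg_e0000074	0.0142
cg_e0000075	0.0115
cg_e0000076	0.0108
cg_e0000077	0.0442
cg_e0000078	0.0092
cg_e0000079	0.0107
cg_e0000080	-0.0267
cg_e0000081	-0.0337
cg_e0000082	0.0731
cg_e0000083	-0.0193
cg_e0000084	0.0156
cg_e0000085	-0.0260
cg_e0000086	-0.0336
cg_e0000087	0.0166
cg_e0000088	-0.0417
cg_e0000089	0.0561
cg_e0000090	0.0026
cg_e0000091	-0.0027
cg_e0000092	0.0042
cg_e0000093	0.0292
cg_e0000094	0.0093
cg_e0000095	-0.0069
cg_e0000096	0.0248
cg_e0000097	-0.0221
cg_e0000098	-0.0238
cg_e0000099	-0.0377
cg_e0000100	0.0355
cg_e0000101	-0.0158
cg_e0000102	-0.0088
cg_e0000103	0.0467
cg_e0000104	0.0323
cg_e0000105	0.0072
cg_e0000106	0.0156
cg_e0000107	-0.0185
cg_e0000108	0.0309
cg_e0000109	0.0097
cg_e0000110	-0.0391
cg_e0000111	-0.0434
cg_e0000112	-0.0702
cg_e0000113	-0.0352
cg_e0000114	-0.0237
cg_e0000115	0.0116
cg_e0000116	0.0523
cg_e0000117	-0.0090
cg_e0000118	-0.0118
cg_e0000119	0.0163
cg_e0000120	-0.0142
cg_e0000121	0.0129
cg_e0000122	-0.0322
cg_e0000123	0.0304
cg_e0000124	0.0189
cg_e0000125	0.0299
cg_e0000126	0.0085
cg_e0000127	0.0275
cg_e0000128	0.0075
cg_e0000129	-0.0668
cg_e0000130	-0.0278
cg_e0000131	0.0413
cg_e0000132	0.0179
cg_e0000133	0.0932
cg_e0000134	-0.0551
cg_e0000135	-0.0106
cg_e0000136	-0.0030
cg_e0000137	0.0176
cg_e0000138	0.0183
cg_e0000139	0.0550
cg_e0000140	-0.0123
cg_e0000141	0.0429
cg_e0000142	-0.0107
cg_e0000143	0.0239
cg_e0000144	0.0380
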