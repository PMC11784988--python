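cpg_id	weight
cg_m0000001	-0.3573
cg_m0000002	-0.0937
cg_m0000003	-0.1214
cg_m0000004	0.0541
cg_m0000005	-0.2278
cg_m0000006	-0.0736
cg_m0000007	0.1031
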