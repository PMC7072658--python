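residue	dE_MM	dG_polar	dG_SASA	dG_bind
Trp418	-4.377	2.3992	-0.4297	-2.4067
Phe38	-2.7748	1.1358	-0.3484	-1.9848
Ile174	-1.4312	0.2321	-0.2701	-1.4684
Ile35	-1.4563	0.3508	-0.2033	-1.3111
Val177	-0.9842	0.2892	-0.1434	-0.8382
Ile306	-1.2814	0.7336	-0.1411	-0.69
Trp441	-2.524	2.0924	-0.2414	-0.6728
Pro150	-0.81	0.3465	-0.0892	-0.5512
Leu414	-1.9582	1.6616	-0.1454	-0.4428
Ala307	-0.7957	0.5096	-0.1578	-0.442
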