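tunnel	location	throughput	cost	bottleneck_radius	length	curvature	bottleneck_residues
37	TM7a-TM8b	0.039658	3.227465	0.855433	84.94969	1.64852	Phe38;Tyr85;Trp441;Asn445
39	TM7a-TM11	0.029718	3.515996	0.855433	85.94388	1.555505	Phe38;Tyr85;Trp441;Asn445
41	TM7a-TM10b	0.024121	3.724671	0.855433	94.43239	1.576965	Phe38;Tyr85;Trp441;Asn445
42	TM2-TM11	0.017327	4.055483	0.855433	98.90193	2.068183	Phe38;Tyr85;Trp441;Asn445
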