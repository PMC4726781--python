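sample_id	rsid	contig	position	ref	alt	genotype	call_rate
S001	rs4244285	chr10	96541616	G	A	G/A	97.2
S001	rs3758581	chr10	96612495	A	G	G/G	99.1
S001	rs1065852	chr22	42526694	G	A	G/G	95.5
S002	rs4244285	chr10	96541616	G	A	G/G	98.4
S002	rs3758581	chr10	96612495	A	G	A/G	92.0
S002	rs1065852	chr22	42526694	G	A
S003	rs4244285			G	A	A/A	88.7
S003	rs3758581	chr10	96612495	A	G	A/A	81.3
S003	rs1065852	chr22	42526694	G	A	G/A	96.9
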