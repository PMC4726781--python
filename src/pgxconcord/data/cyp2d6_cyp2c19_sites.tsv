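gene	region	id	star_allele	tranche
CYP2C19	Upstream region	rs4986894		PASS_99
CYP2C19	Exon 1	rs17885098		PASS_99
CYP2C19	Exon 2	rs17878459		PASS_99
CYP2C19	Intron 2	rs12769205	*35	PASS_99
CYP2C19	Exon 5	rs4244285	*2	PASS_99
CYP2C19	Intron 5	rs28399511		PASS_99
CYP2C19	Intron 5	rs4417205		PASS_99
CYP2C19	Exon 7	rs3758580		PASS_99
CYP2C19	Exon 7	rs3758581		PASS_99
CYP2C19	Intron 7	rs4917623		PASS_99
CYP2C19	Intron 8	rs12268020		PASS_99
CYP2D6	Exon 1	rs72549358	*28	PASS_99
CYP2D6	Exon 1	rs769258	*35	PASS_99
CYP2D6	Exon 1	rs1065852	*10	PASS_99
CYP2D6	Exon 2	rs1081003		PASS_99
CYP2D6	Exon 2	rs28371704		TRANCHE_99_999
CYP2D6	Exon 2	rs28371705		TRANCHE_99_999
CYP2D6	Intron 2	22:42525227A>C		TRANCHE_99_999
CYP2D6	Exon 3	rs1058164		PASS_99
CYP2D6	Exon 3	rs78482768	*28	PASS_99
CYP2D6	Exon 3	rs5030655	*6	PASS_99
CYP2D6	Intron 3	rs3892097	*4	PASS_99
CYP2D6	Exon 4	rs139779104		TRANCHE_99_999
CYP2D6	Exon 4	rs150163869		TRANCHE_99_999
CYP2D6	Exon 4	rs28371713		TRANCHE_99_999
CYP2D6	Intron 4	rs58440431		PASS_99
CYP2D6	Intron 4	rs113889384		TRANCHE_99_999
CYP2D6	Intron 4	rs112568578		TRANCHE_99_999
CYP2D6	Intron 4	rs111564371		TRANCHE_99_999
CYP2D6	Exon 5	rs5030656	*9	PASS_99
CYP2D6	Exon 6	rs16947	*2	PASS_99
CYP2D6	Intron 6	rs28371725	*41	PASS_99
CYP2D6	Exon 7	rs61736517		TRANCHE_99_999
CYP2D6	Exon 7	rs1058172		TRANCHE_99_999
CYP2D6	Intron 7	rs1985842		TRANCHE_99_999
CYP2D6	Intron 7	rs28578778		TRANCHE_99_999
CYP2D6	Intron 7	rs28371729		TRANCHE_99_999
CYP2D6	Intron 7	rs116917064		TRANCHE_99_999
CYP2D6	Exon 8	rs28371732		PASS_99
CYP2D6	Exon 9	rs1135840		PASS_99
CYP2D6	Downstream region	rs77845838		PASS_99
CYP2D6	Downstream region	rs28371738		PASS_99
CYP2D6	Downstream region	22:42522498G>A		TRANCHE_99_999
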