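species	id	forward	reverse	chrom	start_1based	end_1based	declared_length
S_cerevisiae	ACT1	GGTGTCTTGGTCTACCGACG	TGTGTAAAGCCGGTTTTGCC	chrVI	54267	54341	75
S_cerevisiae	ARS307	AGCAGTAGCACATGGACACA	ACTTTCTTGTGTGGGCTGCT	chrIII	108976	109038	63
S_cerevisiae	COX2	TTAAAGTTGATGCTACTCCTGGT	TTTGCATGACCTGTCCCACA	chrM	74341	74449	109
H_sapiens	ACTb	TCCAAAGGAGACTCAGGTCAG	CGCCCTTTCTCACTGGTTC	chr7	5529028	5529100	73
H_sapiens	Tel16	TTCTCCCTCCCCCTTGATT	AGGGACAAAGAAATGGAAGGA	chr16	46619343	46619402	60
H_sapiens	HCN1	CGTGCTCTTGTGCACTTCAT	CAGCAGCAGGTACAGCAGTC	chr5	45262281	45262391	111
H_sapiens	hCOX2	CCCCACCCTACCACACATTC	GCTTGAAACCAGCTTTGGGG	chrM	7399	7487	89
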