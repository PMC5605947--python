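##fileformat=VCFv4.2
##source=hand-constructed-test-fixture
##contig=<ID=1,length=2000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	ind1	ind2	ind3
1	500	rs1	A	G	.	PASS	.	GT	0|1	1|1	0|0
1	1500	rs2	C	T	.	PASS	.	GT	1|0	0|0	0|1
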