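# 13-SNP HDL-C panel retained for the male threshold (HDL-C < 40 mg/dL).
# Only the rsID list and retained status are literature values; allele
# columns are synthetic placeholders and numeric columns are left empty
# because per-SNP weights are fitted in-cohort.
rsid	effect_allele	other_allele	beta	assoc_p	maf	hwe_p	status	reason
rs5882	A	G					retained
rs3764261	A	C					retained
rs1800961	T	C					retained
rs2338104	G	C					retained
rs10850219	G	C					retained
rs1532085	A	G					retained
rs2000813	T	C					retained
rs2156552	T	A					retained
rs17411031	G	C					retained
rs2075440	T	A					retained
rs4660293	G	A					retained
rs7679	C	T					retained
rs13107325	T	C					retained
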