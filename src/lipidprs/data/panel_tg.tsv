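# 19-SNP triglyceride panel (selected from 57 initial candidates).
# Only the rsID list and retained status are literature values; allele
# columns are synthetic placeholders and numeric columns are left empty
# because per-SNP weights are fitted in-cohort.
rsid	effect_allele	other_allele	beta	assoc_p	maf	hwe_p	status	reason
rs2072560	T	C					retained
rs7557067	A	G					retained
rs157582	T	C					retained
rs439401	C	T					retained
rs5128	G	C					retained
rs2068888	G	A					retained
rs10889353	A	C					retained
rs174546	T	C					retained
rs2929282	T	A					retained
rs780092	G	A					retained
rs1260326	T	C					retained
rs2247056	C	T					retained
rs12678919	G	A					retained
rs17145738	C	T					retained
rs1495741	G	A					retained
rs7679	C	T					retained
rs11776767	G	C					retained
rs2954029	A	T					retained
rs998584	A	C					retained
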