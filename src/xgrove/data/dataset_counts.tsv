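subset	n_taxa	n_loci	nt_positions	aa_positions
ahe	111	381	231153	77051
omcl	111	1905	1566147	522049
autosomal	111	2141	1690446	
x	111	145	106854	
mito	101		16008	
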