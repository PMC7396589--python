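feature_id	method	log2fc	pvalue	padj
miR-127-3p	deseq2	3.38		1.27e-7
miR-409-3p	deseq2	6.22		2.25e-7
miR-540-3p	deseq2	3.42		0.0485
miR-410-3p	deseq2	3.08		0.101
miR-541-5p	deseq2	3.32		0.406
miR-329-5p	deseq2	5.13		0.229
miR-30d-3p	deseq2	-4.17		0.580
miR-127-3p	limma	3.77		6.08e-6
miR-409-3p	limma	5.41		4.38e-6
miR-540-3p	limma	3.67		5.0e-3
miR-410-3p	limma	3.49		8.29e-3
miR-541-5p	limma	5.34		2.3e-4
miR-30d-3p	limma	-2.67		0.196
miR-127-3p	edger	3.40	2.14e-4
miR-409-3p	edger	6.16	5.06e-5
miR-540-3p	edger	3.37	1.39e-3
miR-410-3p	edger	3.02	2.49e-3
miR-541-5p	edger	3.24	8.88e-3
miR-329-5p	edger	6.23	1.2e-2
miR-30d-3p	edger	-4.4	5.79e-3
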