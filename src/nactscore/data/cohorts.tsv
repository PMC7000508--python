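accession	n_patients	n_pcr	n_er_pos_her2_neg	n_pcr_er_pos_her2_neg	platform
GSE20271	178	26	89	6	affymetrix_u133a
GSE20194	278	56	140	7	affymetrix_u133a
GSE32646	115	27	55	5	affymetrix_u133plus2
GSE41998	279	69	93	10	affymetrix_u133a2
GSE25066	486	91	268	27	affymetrix_u133a
GSE34138	178	28	119	4	illumina_wg6v3
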