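block_label	block_coords	gene_symbol	hpa_validation	localization	subcellular
GWAS_EOC_54	chr9:135138764-137155444	AK8	Enhanced	Ambiguous	NA
GWAS_EOC_52	chr9:15913285-17915021	BNC2	Approved	Ambiguous	NA
GWAS_EOC_25	chr19:16389703-40732752	BST2	Approved	Ambiguous	NA
GWAS_EOC_30	chr20:56330568-58330569	C20orf85	Enhanced	Ciliated cells	Brush border
GWAS_EOC_46	chr6:150405376-152405377	CCDC170	Enhanced	Ciliated cells	Brush border
GWAS_EOC_52	chr9:15913285-17915021	CCDC171	Uncertain	Ambiguous	NA
GWAS_EOC_12	chr11:85642871-87642872	CCDC81	Uncertain	Ambiguous	NA
GWAS_EOC_38	chr5:279789-2279790	CEP72	Approved	Serous and ciliated cells	NA
GWAS_EOC_20	chr16:83537526-85537527	DNAAF1	Enhanced	Ciliated cells	Cytoplasm and brush border
GWAS_EOC_5	chr1:243240447-245240448	EFCAB2	Approved	Ambiguous	NA
GWAS_EOC_42	chr5:174418048-176418049	FAM153B	Uncertain	Ambiguous	NA
GWAS_EOC_34	chr3:155397748-157435952	GMPS	NA	Not available	NA
GWAS_EOC_23	chr17:42516401-47500673	HOXB3	Approved	Serous and ciliated cells	NA
GWAS_EOC_26	chr19:38732751-40732752	KCNK6	Uncertain	Ambiguous	NA
GWAS_EOC_16	chr14:41173640-43173641	LRFN5	Uncertain	Not detected	NA
GWAS_EOC_37	chr4:184470585-186470586	LRP2BP	Approved	Ciliated cells	Brush border
GWAS_EOC_23	chr17:42516401-47500673	LRRC46	Enhanced	Ciliated cells	Nucleus, cytoplasm and brush border
GWAS_EOC_24	chr17:58880645-61480968	MARCH10	Enhanced	Ciliated cells	Nucleus and blefaroplast
GWAS_EOC_11	chr11:35386754-37386755	PAMR1	NA	Not available	NA
GWAS_EOC_35	chr4:118949959-120949960	PDE5A	Approved	Ambiguous	NA
GWAS_EOC_35	chr4:118949959-120949960	PRSS12	Uncertain	Ambiguous	NA
GWAS_EOC_48	chr7:6108187-8108188	RSPH10B2	Supported	Ciliated cells (not all)	Cytoplasm and brush border
GWAS_EOC_6	chr10:20827795-22915619	SPAG6	Enhanced	Ciliated cells	Cytoplasm and brush border
GWAS_EOC_8	chr11:7404500-9404501	STK33	Uncertain	Ciliated cells (not all)	Cytoplasm
GWAS_EOC_34	chr3:155397748-157435952	TIPARP	Uncertain	Ambiguous	NA
GWAS_EOC_11	chr11:35386754-37386755	TNXB	NA	Not available	NA
GWAS_EOC_38	chr5:279789-2279790	TPPP	Enhanced	Ciliated cells (not all)	Cytoplasm and brush border
GWAS_EOC_1	chr1:21415409-23490724	WNT4	Uncertain	Serous	NA
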