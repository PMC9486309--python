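# Pathways enriched in AMDgset with their candidate-gene (AMDgset) members,
# transcribed from the source study's pathway-enrichment table (24 rows).
complement_and_coagulation_cascades	Complement and coagulation cascades	CFH	VTN	CFI	F13B	CFB	CFD	SERPING1	C2	C3	C4A	C9
fluid_shear_stress_and_atherosclerosis	Fluid shear stress and atherosclerosis	HMOX1	HMOX2	GSTM1	NFE2L2	NQO1	CCL2	KDR	TNF	MMP2	MMP9	IL1B	NOS3	VEGFA
hif_1_signaling_pathway	HIF-1 signaling pathway	FLT1	ANGPT2	HMOX1	TF	TFRC	IGF1R	TLR4	NOS2	NOS3	VEGFA
cytokine_cytokine_receptor_interaction	Cytokine-cytokine receptor interaction	FLT1	IL17A	IL17RC	TNFRSF10A	CCR2	TGFBR1	CCL2	KDR	CCR3	TNF	IL1B	PRLR	CX3CR1	CXCL8	VEGFA
plasma_membrane_estrogen_receptor_signaling	Plasma membrane estrogen receptor signaling	ESR1	IGF1R	MMP2	MMP9	NOS3
cells_and_molecules_involved_in_local_acute_inflammatory_response	Cells and Molecules involved in local acute inflammatory response	SELP	C3	TNF	CXCL8
pi3k_akt_signaling_pathway	PI3K-Akt signaling pathway	COL4A3	FLT1	VTN	ANGPT2	PGF	RXRA	IGF1R	TLR2	TLR4	KDR	TNXB	NOS3	PRLR	VEGFA
il23_mediated_signaling_events	IL23-mediated signaling events	IL17A	CCL2	TNF	IL1B	NOS2
phagosome	Phagosome	HLA-B	HLA-DQB1	TFRC	FCGR2A	CD36	SCARB1	TLR2	TLR4	C3
ensemble_of_genes_encoding_core_extracellular_matrix_including_ecm_glycoproteins_collagens_and_proteoglycans	Ensemble of genes encoding core extracellular matrix including ECM glycoproteins, collagens and proteoglycans	COL4A3	COL8A1	COL10A1	FBLN5	VTN	COL15A1	GAS6	KERA	HMCN1	ELN	FGL1	TNXB
fat_digestion_and_absorption	Fat digestion and absorption	ABCA1	CD36	SCARB1	NPC1L1	ABCG8
il_17_signaling_pathway	IL-17 signaling pathway	IL17A	IL17RC	CCL2	TNF	MMP9	IL1B	CXCL8
genes_encoding_enzymes_and_their_regulators_involved_in_the_remodeling_of_the_extracellular_matrix	Genes encoding enzymes and their regulators involved in the remodeling of the extracellular matrix	HTRA1	SERPINF1	MMP20	F13B	TIMP3	ADAMTS9	LOXL1	CST3	SERPING1	MMP2	MMP9
free_radical_induced_apoptosis	Free Radical Induced Apoptosis	GPX1	TNF	CXCL8
integrins_in_angiogenesis_amb2_integrin_signaling	Integrins in angiogenesis amb2 Integrin signaling	COL4A3	VTN	IGF1R	KDR	VEGFA
mineral_absorption	Mineral absorption	SELP	VTN	TNF	MMP2	MMP9
vegf_hypoxia_and_angiogenesis	VEGF, Hypoxia, and Angiogenesis	HMOX1	HMOX2	TF	MT2A	VDR
adhesion_and_diapedesis_of_granulocytes	Adhesion and Diapedesis of Granulocytes	FLT1	KDR	NOS3	VEGFA
mechanism_of_gene_regulation_by_peroxisome_proliferators_via_ppara_alpha	Mechanism of Gene Regulation by Peroxisome Proliferators via PPARa(alpha)	SELP	TNF	CXCL8
cytokines_can_induce_activation_of_matrix_metalloproteinases_which_degrade_extracellular_matrix	Cytokines can induce activation of matrix metalloproteinases, which degrade extracellular matrix	RXRA	PPARGC1A	CD36	TNF	NOS2
the_igf_1_receptor_and_longevity	The IGF-1 Receptor and Longevity	ACE	TNF	IL1B
hif_2_alpha_transcription_factor_network	HIF-2-alpha transcription factor network	IGF1R	SOD2	SOD3
toll_like_receptor_signaling_pathway	Toll-like receptor signaling pathway	FLT1	SIRT1	KDR	VEGFA
ensemble_of_genes_encoding_ecm_associated_proteins_including_ecm_affilaited_proteins_ecm_regulators_and_secreted_factors	Ensemble of genes encoding ECM-associated proteins including ECM-affilaited proteins, ECM regulators and secreted factors	TLR2	TLR3	TLR4	TNF	IL1B	CXCL8
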