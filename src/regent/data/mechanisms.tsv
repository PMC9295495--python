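region_class	mechanism	vep_categories	predictor_class	exemplar
promoter	tf_binding_alteration	upstream_gene_variant,regulatory_region_variant,TF_binding_site_variant	TFBS disruption e.g. motifbreakR/SEMpl/QBiC-Pred	GATA1:-113A>G (hereditary persistence of foetal haemoglobin)
promoter	transcription_alteration	upstream_gene_variant,5_prime_UTR_variant	reporter assay	CHM:c.-98C>A (choroideremia)
promoter	methylation_alteration	upstream_gene_variant,5_prime_UTR_variant	bisulphite sequencing	BRCA1:c.-107A>T (breast and ovarian cancer)
five_prime_utr	uAUG_creation	5_prime_UTR_variant	uORF annotators e.g. UTRannotator	NF1:c.-272G>A (neurofibromatosis type 1)
five_prime_utr	uORF_perturbation	5_prime_UTR_variant	uORF annotators e.g. UTRannotator	NF2:-66-65insT (neurofibromatosis type 2)
five_prime_utr	IRES_disruption	5_prime_UTR_variant	IRES predictors e.g. IRESpy/IRESfinder	GJB1:c.-103C>T (Charcot-Marie-Tooth disease)
five_prime_utr	splice_disruption	5_prime_UTR_variant	splicing predictors e.g. SpliceAI	SHOX:c.-19G>A (SHOX haploinsufficiency)
five_prime_utr	kozak_alteration	5_prime_UTR_variant	Kozak annotators e.g. utR.annotation	GATA4:c.-6G>C (atrial septal defect)
five_prime_utr	n_terminal_elongation	5_prime_UTR_variant	uORF annotators e.g. UTRannotator	MEF2C:c.-8C>T (developmental disorder)
intron	canonical_splice_disruption	splice_donor_variant,splice_acceptor_variant,splice_region_variant,splice_donor_5th_base_variant,splice_polypyrimidine_tract_variant	splicing predictors e.g. SpliceAI	MYBPC3:c.3490+1G>A (hypertrophic cardiomyopathy)
intron	branchpoint	intron_variant	splicing predictors e.g. SpliceAI	HNF4A:c.264-21A>G (MODY); BBS1:c.592-21A>T (retinitis pigmentosa)
intron	pseudo_exon_activation	intron_variant	splicing predictors e.g. SpliceAI	DMD:c.7310-19A>G (muscular dystrophy)
intron	poison_exon_inclusion	intron_variant	splicing predictors e.g. SpliceAI	SCN1A:c.4002+2165C>T (Dravet syndrome)
intron	splice_motif_spacing	intron_variant	splicing predictors e.g. SpliceAI	DOK7:c.54+8_54+17del
intron	cryptic_exon	intron_variant	splicing predictors e.g. SpliceAI	VHL (erythrocytosis)
three_prime_utr	polyA_signal_disruption	3_prime_UTR_variant	polyA predictors e.g. Omni-PolyA	NAA10:c.*43A>G (microphthalmia)
three_prime_utr	miRNA_site_disruption	3_prime_UTR_variant	miRNA target resources e.g. miRTarBase	REEP1 (hereditary spastic paraplegia)
three_prime_utr	splice_disruption	3_prime_UTR_variant	splicing predictors e.g. SpliceAI	LHFPL5:c.*16+1G>A (hearing impairment)
cre	tf_binding_alteration	regulatory_region_variant,TF_binding_site_variant,TFBS_ablation,TFBS_amplification,upstream_gene_variant,downstream_gene_variant,intergenic_variant	TFBS disruption e.g. motifbreakR/SEMpl/QBiC-Pred	chr7:155754267:C>T (holoprosencephaly)
cre	enhancer_disruption	regulatory_region_variant,regulatory_region_ablation,regulatory_region_amplification	reporter assay / deletion tiling	PTF1A distal enhancer (isolated pancreatic agenesis); SOX9 (Pierre Robin sequence)
other	new_regulatory_element	intergenic_variant,upstream_gene_variant,downstream_gene_variant	none established	chr16:209709T>C (alpha-thalassaemia)
other	mirna_seed	non_coding_transcript_exon_variant,mature_miRNA_variant	miRNA target resources	miR-204:n.37C>T (retinal dystrophy)
other	snrna_structure	non_coding_transcript_exon_variant,non_coding_transcript_variant	splicing predictors e.g. SpliceAI	RNU12 (cerebellar ataxia); RNU4ATAC (Roifman syndrome); SNORD118
other	tad_boundary_disruption	intergenic_variant	chromatin interaction assays	WNT6/IHH/EPHA4/PAX3 locus (limb phenotypes)
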