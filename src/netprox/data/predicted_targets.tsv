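target_id	symbol	protein_name	uniprot_id
Tar001	ABCB1	ATP-dependent translocase ABCB1	P08183
Tar002	ABCC1	Multidrug resistance-associated protein 1	P33527
Tar003	ABCG2	Broad substrate specificity ATP-binding cassette transporter ABCG2	Q9UNQ0
Tar004	ACHE	Acetylcholinesterase (AChE)	P22303
Tar005	ADORA1	Adenosine receptor A1	P30542
Tar006	ADORA2A	Adenosine receptor A2a	P29274
Tar007	ADORA3	Adenosine receptor A3	P0DMS8
Tar008	ADRA2C	Alpha-2C adrenergic receptor	P18825
Tar009	AKR1B1	Aldo-keto reductase family 1 member B1	P15121
Tar010	AKR1B10	Aldo-keto reductase family 1 member B10	O60218
Tar011	AKR1C2	Aldo-keto reductase family 1 member C2	P52895
Tar012	AKR1D1	Aldo-keto reductase family 1 member D1	P51857
Tar013	ALB	Albumin	P02768
Tar014	ALOXE3	Hydroperoxide isomerase ALOXE3	Q9BYJ1
Tar015	ALPI	Intestinal-type alkaline phosphatase	P09923
Tar016	APOB	Apolipoprotein B-100	P04114
Tar017	ATM	Serine-protein kinase ATM	Q13315
Tar018	BDNF	Brain-derived neurotrophic factor	P23560
Tar019	CA1	Carbonic anhydrase 1	P00915
Tar020	CA12	Carbonic anhydrase 12	O43570
Tar021	CA13	Carbonic anhydrase 13	Q8N1Q1
Tar022	CA14	Carbonic anhydrase 14	Q9ULX7
Tar023	CA2	Carbonic anhydrase 2	P00918
Tar024	CA3	Carbonic anhydrase 3	P07451
Tar025	CA4	Carbonic anhydrase 4	P22748
Tar026	CA5A	Carbonic anhydrase 5A	P35218
Tar027	CA5B	Carbonic anhydrase 5B	Q9Y2D0
Tar028	CA6	Carbonic anhydrase 6	P23280
Tar029	CA7	Carbonic anhydrase 7	P43166
Tar030	CA9	Carbonic anhydrase 9	Q16790
Tar031	CASP3	Caspase-3	P42574
Tar032	CAT	Catalase	P04040
Tar033	CBR1	Carbonyl reductase [NADPH] 1	P16152
Tar034	CCL2	C-C motif chemokine 2	P13500
Tar035	CES4A	Carboxylesterase 4A	Q5XG92
Tar036	CES5A	Carboxylesterase 5A	Q6NT32
Tar037	CSNK2A1	Casein kinase II subunit alpha	P68400
Tar038	CTDSP1	Carboxy-terminal domain RNA polymerase II polypeptide A small phosphatase 1	Q9GZU7
Tar039	CYP19A1	Aromatase	P11511
Tar040	CYP1A1	Cytochrome P450 1A1	P04798
Tar041	CYP1A2	Cytochrome P450 1A2	P05177
Tar042	CYP1B1	Cytochrome P450 1B1	Q16678
Tar043	CYP2C9	Cytochrome P450 2C9	P11712
Tar044	CYP2E1	Cytochrome P450 2E1	P05181
Tar045	CYP3A4	Cytochrome P450 3A4	P08684
Tar046	DECR1	2,4-Dienoyl-CoA reductase	Q16698
Tar047	DNM1L	Dynamin-1-like protein	O00429
Tar048	EIF2AK3	Eukaryotic translation initiation factor 2-alpha kinase 3	Q9NZJ5
Tar049	ELANE	Neutrophil elastase	P08246
Tar050	ERAP1	Endoplasmic reticulum aminopeptidase 1	Q9NZ08
Tar051	FTO	Alpha-ketoglutarate-dependent dioxygenase FTO	Q9C0B1
Tar052	FUT7	Alpha-(1,3)-fucosyltransferase 7	Q11130
Tar053	GATA3	Trans-acting T-cell-specific transcription factor GATA-3	P23771
Tar054	GFER	FAD-linked sulfhydryl oxidase ALR	P55789
Tar055	GGCX	Vitamin K-dependent gamma-carboxylase	P38435
Tar056	GLP1R	Glucagon-like peptide 1 receptor	P43220
Tar057	GSK3B	Glycogen synthase kinase-3 beta	P49841
Tar058	HMOX1	Heme oxygenase 1	P09601
Tar059	HSD17B1	Estradiol 17-beta-dehydrogenase 1	P14061
Tar060	IKBKB	Inhibitor of nuclear factor kappa-B kinase subunit beta	O14920
Tar061	IL6	Interleukin-6	P05231
Tar062	JUN	Transcription factor AP-1	P05412
Tar063	LDLR	Low-density lipoprotein receptor	P01130
Tar064	MITF	Microphthalmia-associated transcription factor	O75030
Tar065	MMP2	Matrix metalloproteinase-2	P08253
Tar066	MMP7	Matrix metalloproteinase-7	P09237
Tar067	MPO	Myeloperoxidase	P05164
Tar068	NFKB1	Nuclear factor NF-kappa-B p105 subunit	P19838
Tar069	NOS2	Nitric oxide synthase	P35228
Tar070	NOX4	NADPH oxidase 4	Q9NPH5
Tar071	NPR1	Atrial natriuretic peptide receptor 1	P16066
Tar072	P4HB	Protein disulfide-isomerase	P07237
Tar073	PPARA	Peroxisome proliferator-activated receptor alpha	Q07869
Tar074	PPARG	Peroxisome proliferator-activated receptor gamma	P37231
Tar075	PTGS1	Prostaglandin G/H synthase 1	P23219
Tar076	PTGS2	Prostaglandin G/H synthase 2	P35354
Tar077	RAPGEF1	Rap guanine nucleotide exchange factor 1	Q13905
Tar078	RELA	Transcription factor p65	Q04206
Tar079	RXRA	Retinoic acid receptor RXR-alpha	P19793
Tar080	SCD	Acyl-CoA desaturase	O00767
Tar081	SELE	E-selectin	P16581
Tar082	SERPINE1	Plasminogen activator inhibitor 1	P05121
Tar083	SHBG	Sex hormone-binding globulin	P04278
Tar084	SLC16A1	Monocarboxylate transporter 1	P53985
Tar085	SLC22A10	Solute carrier family 22 member 10	Q63ZE4
Tar086	SLC22A11	Solute carrier family 22 member 11	Q9NSA0
Tar087	SLC22A6	Solute carrier family 22 member 6	Q4U2R8
Tar088	SLC22A7	Solute carrier family 22 member 7	Q9Y694
Tar089	SLC22A8	Solute carrier family 22 member 8	Q8TCC7
Tar090	SLCO2B1	Solute carrier organic anion transporter family member 2B1	O94956
Tar091	TTR	Transthyretin	P02766
Tar092	TYR	Tyrosinase	P14679
Tar093	UCP1	Mitochondrial brown fat uncoupling protein 1	P25874
Tar094	UGT1A1	UDP-glucuronosyltransferase 1A1	P22309
Tar095	UGT1A10	UDP-glucuronosyltransferase 1A10	Q9HAW8
Tar096	UGT1A3	UDP-glucuronosyltransferase 1A3	P35503
Tar097	UGT1A6	UDP-glucuronosyltransferase 1-6	Q64435
Tar098	UGT1A7	UDP-glucuronosyltransferase 1A7	Q9HAW7
Tar099	UGT1A8	UDP-glucuronosyltransferase 1A8	Q9HAW9
Tar100	UGT1A9	UDP-glucuronosyltransferase 1A9	Q62452
Tar101	UGT2B15	UDP-glucuronosyltransferase 2B15	P54855
Tar102	UGT2B17	UDP-glucuronosyltransferase 2B17	O75795
Tar103	VCAM1	Vascular cell adhesion protein 1	P19320
Tar104	VEGFA	Vascular endothelial growth factor A	P15692
Tar105	XDH	Xanthine dehydrogenase/oxidase	P47989
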