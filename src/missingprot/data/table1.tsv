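group	accession	chromosome	gene_name	protein_name	gene_id	evidence_label
III	P0CG40	2	SP9	Transcription factor Sp9	ENSG00000217236	Evidence at protein level
III	Q6ZWH5	3	NEK10-016	Serine/threonine-protein kinase Nek10	ENSG00000163491	Evidence at protein level
III	Q7Z407	8	CSMD3-006	CUB and sushi domain-containing protein 3	ENSG00000164796	Evidence at protein level
IV	Q8N9H9	1	C1ORF127-001	Uncharacterized protein C1orf127	ENSG00000175262	Evidence at transcript level
IV	Q8TAY7	1	FAM110D	Protein FAM110D	ENSG00000197245	Evidence at transcript level
IV	Q6UY18	1	LINGO4	Leucine-rich repeat and immunoglobulin-like domain-containing nogo receptor-interacting protein 4	ENSG00000213171	Evidence at transcript level
IV	Q8N7P1	1	PLD5-006	Inactive phospholipase D5	ENSG00000180287	Evidence at transcript level
IV	A6NCL1	3	GMNC-001	Geminin coiled-coil domain-containing protein 1	ENSG00000205835	Evidence at protein level
IV	Q6ZWH5	3	NEK10-015	Serine/threonine-protein kinase Nek10	ENSG00000163491	Evidence at protein level
IV	Q6ZU67	4	BEND4-001	BEN domain-containing protein 4	ENSG00000188848	Evidence at protein level
IV	Q4ZJI4	4	SLC9B1-002	Sodium/hydrogen exchanger 9B1	ENSG00000164037	Evidence at protein level
IV	Q9H1J5	5	WNT8A	Protein Wnt-8a	ENSG00000061492	Evidence at transcript level
IV	Q96LW1	5	ZNF354B	Zinc finger protein 354B	ENSG00000178338	Evidence at transcript level
IV	Q8IXS0	6	FAM217A-001	Protein FAM217A	ENSG00000145975	Evidence at transcript level
IV	C9J798	7	RASA4B-201	Ras GTPase-activating protein 4B	ENSG00000170667	Protein inferred from homology
IV	Q8TE58	11	ADAMTS15	A disintegrin and metalloproteinase with thrombospondin motifs 15	ENSG00000166106	Evidence at transcript level
IV	Q8N4L1	11	TMEM151A	Transmembrane protein 151A	ENSG00000179292	Evidence at protein level
IV	Q9H2C1	12	LHX5	LIM/homeobox protein Lhx5	ENSG00000089116	Evidence at transcript level
IV	Q96LU7	12	MYRFL-003	Myelin regulatory factor-like protein	ENSG00000166268	Evidence at transcript level
IV	P46721	12	SLCO1A2	Solute carrier organic anion transporter family member 1A2	ENSG00000084453	Evidence at protein level
IV	Q7RTS6	17	OTOP2-201	Otopetrin-2	ENSG00000183034	Evidence at transcript level
IV	Q6ZSJ9	17	SHISA6-003	Protein shisa-6 homolog	ENSG00000188803	Evidence at protein level
IV	Q8NFU1	19	BEST2-002	Bestrophin-2	ENSG00000039987	Evidence at transcript level
IV	Q9BTN0	19	LRFN3-001	Leucine-rich repeat and fibronectin type-III domain-containing protein 3	ENSG00000126243	Evidence at protein level
IV	Q9HCL3	19	ZFP14-001	Zinc finger protein 14 homolog	ENSG00000142065	Evidence at transcript level
IV	P25100	20	ADRA1D-001	Alpha-1D adrenergic receptor	ENSG00000171873	Evidence at protein level
IV	Q8TDG2	23×	ACTRT1	Actin-related protein T1	ENSG00000123165	Evidence at protein level
IV	Q5QGS0	23×	KIAA2022-001	Protein KIAA2022	ENSG00000050030	Evidence at transcript level
IV	Q96NR3	23×	PTCHD1-201	Patched domain-containing protein 1	ENSG00000165186	Evidence at transcript level
V	A6NM62	1	LRRC53	Leucine-rich repeat-containing protein 53	ENSG00000162621	Protein predicted
V	O75325	1	LRRN2-003	Leucine-rich repeat neuronal protein 2	ENSG00000170382	Evidence at transcript level
V	A6NKT7	2	RGPD3-201	RanBP2-like and GRIP domain-containing protein 3	ENSG00000153165	Protein predicted
V	Q9Y691	3	KCNMB2-001	Calcium-activated potassium channel subunit beta-2	ENSG00000275163	Evidence at protein level
V	Q86VZ2	3	WDR5B-001	WD repeat-containing protein 5B	ENSG00000196981	Evidence at protein level
V	Q15270	4	NKX1-1-001	NK1 transcription factor-related protein 1	ENSG00000235608	Evidence at transcript level
V	Q16594	5	AK6	Transcription initiation factor TFIID subunit 9	ENSG00000273841	Evidence at protein level
V	A6NJ46	8	NKX6-3-001	Homeobox protein Nkx-6.3	ENSG00000165066	Evidence at transcript level
V	Q96LD1	8	SGCZ-001	Zeta-sarcoglycan	ENSG00000185053	Evidence at transcript level
V	O76050	10	NEURL1-001	E3 ubiquitin-protein ligase NEURL1	ENSG00000107954	Evidence at protein level
V	Q01851	13	POU4F1	POU domain, class 4, transcription factor 1	ENSG00000152192	Evidence at protein level
V	Q9UBN1	17	CACNG4-001	Voltage-dependent calcium channel gamma-4 subunit	ENSG00000075461	Evidence at protein level
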