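group	group_gene_count	term_id	category	definition	coherence_percent	p_value
A	43	GO:0030528	MF	Transcription regulator activity	100	2.50E-27
A	43	GO:0045449	BP	Regulation of transcription	100	7.60E-22
A	43	GO:0007517	BP	Muscle organ development	15.4	5.50E-05
A	43	GO:0007519	BP	Skeletal muscle tissue development	7.7	1.30E-02
A	43	GO:0055123	BP	Digestive system development	7.7	1.30E-02
A	43	GO:0014706	BP	Striated muscle tissue development	7.7	1.30E-02
A	43	GO:0043282	BP	Pharyngeal muscle development	7.7	1.30E-02
A	43	GO:0002074	BP	Extraocular skeletal muscle development	7.7	1.30E-02
A	43	GO:0048741	BP	Skeletal muscle fiber development	7.7	1.30E-02
A	43	GO:0048747	BP	Muscle fiber development	7.7	1.30E-02
A	43	GO:0060538	BP	Skeletal muscle organ development	7.7	1.30E-02
A	43	GO:0060465	BP	Pharynx development	7.7	1.30E-02
A	43	GO:0007423	BP	Sensory organ development	11.5	1.70E-02
A	43	GO:0042692	BP	Muscle cell differentiation	7.7	2.00E-02
A	43	GO:0060537	BP	Muscle tissue development	7.7	2.00E-02
A	43	GO:0051146	BP	Striated muscle cell differentiation	7.7	2.00E-02
A	43	GO:0055002	BP	Striated muscle cell development	7.7	2.00E-02
A	43	GO:0055001	BP	Muscle cell development	7.7	2.00E-02
A	43	GO:0003677	MF	DNA binding	26.9	8.70E-02
B	267	GO:0030528	MF	Transcription regulator activity	100	8.10E-20
B	267	GO:0045449	BP	Regulation of transcription	100	6.90E-16
B	267	GO:0035257	MF	Nuclear hormone receptor binding	10.5	1.20E-02
B	267	GO:0051427	MF	Hormone receptor binding	10.5	1.60E-02
B	267	GO:0003713	MF	Transcription coactivator activity	10.5	2.00E-02
B	267	GO:0003712	MF	Transcription cofactor activity	10.5	3.10E-02
B	267	GO:0008134	MF	Transcription factor binding	10.5	6.90E-02
B	267	GO:0006355	BP	Regulation of transcription, DNA-dependent	26.3	9.70E-02
C	11	GO:0006350	BP	Transcription	100	1.40E-07
C	11	GO:0030528	MF	Transcription regulator activity	100	4.70E-07
C	11	GO:0006355	BP	Regulation of transcription, DNA-dependent	100	9.50E-07
C	11	GO:0051252	BP	Regulation of RNA metabolic process	100	1.00E-06
C	11	GO:0003677	MF	DNA binding	100	4.10E-06
C	11	GO:0045449	BP	Regulation of transcription	100	9.30E-06
C	11	GO:0003700	MF	Transcription factor activity	71.4	1.70E-04
C	11	KEGG_Id:480089074	KEGG pathway	Circadian rhythm	28.6	3.90E-03
D	3	None	None	None	None	None
E	15	GO:0030528	MF	Transcription regulator activity	100	1.30E-16
E	15	GO:0045449	BP	Regulation of transcription	100	2.40E-13
E	15	GO:0006350	BP	Transcription	68.8	7.90E-09
E	15	GO:0003677	MF	DNA binding	75	1.10E-07
E	15	GO:0006355	BP	Regulation of transcription, DNA-dependent	68.8	1.70E-07
E	15	GO:0051252	BP	Regulation of RNA metabolic process	68.8	1.90E-07
E	15	GO:0016564	MF	Transcription repressor activity	31.2	2.90E-07
E	15	GO:0000122	BP	Negative regulation of transcription from RNA polymerase II promoter	25	1.80E-05
E	15	GO:0009792	BP	Embryonic development ending in birth or egg hatching	25	7.50E-05
E	15	GO:0043009	BP	Chordate embryonic development	25	7.50E-05
E	15	GO:0045892	BP	Negative regulation of transcription, DNA-dependent	25	1.60E-04
E	15	GO:0051253	BP	Negative regulation of RNA metabolic process	25	1.80E-04
E	15	GO:0046982	MF	Protein heterodimerization activity	18.8	2.10E-04
E	15	GO:0021915	BP	Neural tube development	18.8	2.20E-04
E	15	GO:0016481	BP	Negative regulation of transcription	25	2.80E-04
E	15	GO:0007219	BP	Notch signaling pathway	18.8	3.10E-04
E	15	GO:0051172	BP	Negative regulation of nitrogen compound metabolic process	25	3.70E-04
E	15	GO:0045934	BP	Negative regulation of nucleobase, nucleoside, nucleotide and nucleic acid metabolic process	25	3.70E-04
E	15	GO:0031327	BP	Negative regulation of cellular biosynthetic process	25	4.60E-04
E	15	GO:0010558	BP	Negative regulation of macromolecule biosynthetic process	25	4.60E-04
E	15	GO:0009890	BP	Negative regulation of biosynthetic process	25	5.00E-04
E	15	GO:0010629	BP	Negative regulation of gene expression	25	5.70E-04
E	15	GO:0006357	BP	Regulation of transcription from RNA polymerase II promoter	25	8.90E-04
E	15	GO:0010605	BP	Negative regulation of macromolecule metabolic process	25	9.50E-04
E	15	KEGG_Id:480089058	KEGG pathway	TGF-beta signaling pathway	18.8	2.40E-03
E	15	GO:0033504	BP	Floor plate development	12.5	7.90E-03
E	15	GO:0046983	MF	Protein dimerization activity	18.8	9.20E-03
E	15	GO:0048635	BP	Negative regulation of muscle development	12.5	1.20E-02
E	15	GO:0048634	BP	Regulation of muscle development	12.5	1.60E-02
E	15	KEGG_Id:480089056	KEGG pathway	Notch signaling pathway	12.5	4.60E-02
F	4	None	None	None	None	None
Orphan	2	None	None	None	None	None
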