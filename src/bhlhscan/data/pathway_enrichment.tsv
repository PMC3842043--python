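term	source	db_id	sample_hits	background_hits	raw_p	corrected_p	genes
Circadian rhythm: mammal	KEGG	xtr04710	3	21	1.10E-05	0.0001219	XSBmal2; XSDec2; XSClock
TGF-beta signaling pathway	KEGG	xtr04350	4	73	1.52E-05	0.0001219	XSId3; XSId2; XSId4; XSnMyc
Notch signaling pathway	PANTHER	P00045	2	5	0.0004516	0.0024084	XSHes1a; XSHes1b; XSHerp1
Notch signaling pathway	KEGG	xtr04330	2	43	0.0037667	0.0150668	XSHes1a; XSHes1b; XSHes5a
Developmental biology	Reactome	None	2	106	0.0145401	0.0398896	XSHes1a; XSHes1b; XSNDF1; XSNDF2
Circadian clock	Reactome	None	1	8	0.0149586	0.0398896	XSClock
Herpes simplex infection	KEGG	xtr05168	2	128	0.0304156	0.0695215	XSBmal2; XSClock
MAPK signaling pathway	KEGG	xtr04010	2	220	0.0802242	0.1604484	XSMAX; XSnMyc
Fanconi anemia pathway	KEGG	xtr03460	1	51	0.1044307	0.1856547	XSHes1a; XSHes1b
ErbB signaling pathway	KEGG	xtr04012	1	70	0.1406256	0.2250009	XSnMyc
Melanogenesis	KEGG	xtr04916	1	86	0.1700261	0.2386888	XSMITF
Jak-STAT signaling pathway	KEGG	xtr04630	1	91	0.1790166	0.2386888	XSnMyc
Metabolism	Reactome	None	2	458	0.206835	0.2544026	XSSRC2; XSSRC1
Cell cycle	KEGG	xtr04110	1	116	0.2226023	0.2544026	XSnMyc
Wnt signaling pathway	KEGG	xtr04310	1	131	0.2476916	0.2642044	XSnMyc
Wnt signaling pathway	PANTHER	P00057	1	37	0.2756772	0.2756772	XSvMyc
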