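accession	is_duplicate
NP_001096226.2	False
NP_989390.1	False
NP_001096298.1	False
NP_001037951.1	False
NP_001107462.1	False
NP_001107508.1	False
NP_001120597.1	False
NP_001120597.1	True
XP_002931994.1	False
XP_002932187.1	False
XP_002933181.1	False
XP_002934026.1	False
XP_002934312.1	False
XP_002935013.1	False
XP_002935182.1	False
XP_002935886.1	False
XP_002935887.1	False
XP_002936042.1	False
XP_002937330.1	False
XP_002937913.1	False
XP_002938491.1	False
XP_002938497.1	False
XP_002938975.1	False
XP_002939165.1	False
XP_002940290.1	False
XP_002940370.1	False
XP_002941575.1	False
XP_002942929.1	False
XP_002943245.1	False
XP_002944430.1	False
XP_002944506.1	False
XP_002944648.1	False
XP_002944649.1	False
XP_002939654.1	False
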