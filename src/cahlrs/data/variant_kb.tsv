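name	classification	phenotype	allele_tally
c.293-13C>G	P	SW	7
c.518T>A	P	SV	7
c.1069C>T	P	SW	1
c.740del	P	SW	1
c.844G>T	P	NC	1
c.923dup	P	SW	1
c.92C>T	P	unknown	1
c.955C>T	P	SW	1
CYP21A1P/CYP21A2_CH-1	P	SW	1
CYP21A1P/CYP21A2_CH-8	P	SW	1
TNXA/TNXB_CH-1	P	SW	1
c.*1215C>T	VUS	unknown	0
c.*1316C>T	VUS	unknown	0
c.*1351G>C	LP	unknown	0
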