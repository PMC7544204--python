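complex_id	name	members
CBC	Nuclear cap-binding complex	NCBP1;NCBP2
CBCA	CBC-ARS2 complex	NCBP1;NCBP2;SRRT
EJC	Exon junction core complex	EIF4A3;MAGOH;RBM8A;CASC3
THO	THO/TREX complex	THOC1;THOC2;THOC3;THOC5;THOC6;THOC7;DDX39B;ALYREF
NEXT	Nuclear exosome targeting complex	ZCCHC8;RBM7;MTREX
SMN	SMN complex	SMN1;GEMIN2;GEMIN4;GEMIN5;GEMIN6;GEMIN7;GEMIN8;STRAP
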