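# Damaging-missense FBN1 variants observed in congenital-scoliosis cases
# (GRCh37 chromosome 15; transcript NM_000138.4, protein NP_000129.3).
# One row per carrier: c.2613A>C (p.Leu871Phe) recurs in two unrelated
# subjects.  Genomic ref/alt are minus-strand complements of the cDNA
# change.  af_gnomAD is empty when the variant is absent from gnomAD.
subject_id	chrom	pos	ref	alt	gene	consequence	cdna_change	protein_change	protein_pos	domain	cadd	af_gnomAD
XH1162	15	48902987	G	C	FBN1	missense	c.284C>G	p.Ser95Trp	95	EGF-like #01	22.7
XH810	15	48807596	C	A	FBN1	missense	c.1456G>T	p.Gly486Trp	486	EGF-like #04	24.6
XH152	15	48805763	G	T	FBN1	missense	c.1571C>A	p.Thr524Lys	524	cbEGF-like #03	32
XH73	15	48787384	T	G	FBN1	missense	c.2613A>C	p.Leu871Phe	871	Hybrid motif #02	23.9	0.00000406
XH579	15	48787384	T	G	FBN1	missense	c.2613A>C	p.Leu871Phe	871	Hybrid motif #02	23.9	0.00000406
XH766	15	48779535	A	C	FBN1	missense	c.3437T>G	p.Leu1146Arg	1146	cbEGF-like #13	26.4
XH902	15	48729214	C	T	FBN1	missense	c.6440G>A	p.Gly2147Asp	2147	cbEGF-like #32	34
XH441	15	48722914	G	C	FBN1	missense	c.6825C>G	p.Ile2275Met	2275	cbEGF-like #35	20.6
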