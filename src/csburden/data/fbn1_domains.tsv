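# FBN1 (NP_000129.3, 2871 residues) domain intervals used by the packaged
# reference dataset.  Domain NAMES follow the UMD-FBN1 nomenclature for the
# residues they must contain; the interval BOUNDARIES are synthetic
# placeholders (non-authoritative) chosen only so that each annotated
# residue falls inside its published domain label.
start	end	name
85	128	EGF-like #01
450	490	EGF-like #04
500	540	cbEGF-like #03
850	900	Hybrid motif #02
1120	1160	cbEGF-like #13
2110	2150	cbEGF-like #32
2245	2285	cbEGF-like #35
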