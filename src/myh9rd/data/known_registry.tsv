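hgvs_p	residue	classification
p.(Trp33Cys)	33	pathogenic
p.(Lys74Glu)	74	pathogenic
p.(Asn93Lys)	93	pathogenic
p.(Ala95Thr)	95	pathogenic
p.(Ser96Lys)	96	pathogenic
p.(Lys373Asn)	373	pathogenic
p.(Arg702Cys)	702	pathogenic
p.(Arg718Trp)	718	pathogenic
p.(Pro836Lys)	836	pathogenic
p.(Arg1165Cys)	1165	pathogenic
p.(Asp1424Asn)	1424	pathogenic
p.(Asp1424Tyr)	1424	pathogenic
p.(Asp1447Val)	1447	pathogenic
p.(Glu1841Lys)	1841	pathogenic
p.(Gly1924Argfs*21)	1924	pathogenic
p.(Arg1933*)	1933	pathogenic
p.(Met1934Trpfs*14)	1934	pathogenic
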