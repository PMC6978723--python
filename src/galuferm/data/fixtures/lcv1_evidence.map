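# Evidence map for L. suebicus LCV1: pathway evidence key -> UniProt ids.
# Multiple ids on a line are paralogs; any detected paralog covers the
# reaction. uxuA, kdgK and kdgA have annotated genes but no identified
# protein product (ND in the proteome), hence empty lists.
# The mannonate kinase (mak) and 6-phosphomannonate 2-epimerase (mpe)
# activities have no resolved structural gene; their lines are candidate
# tier (gluconate-kinase homologs; epimerase homolog) and are reported but
# never counted toward pathway completeness.
uxaC: A0A0R1WA62 A0A0R1WAR4
uxaE: A0A0R1W3Z7
uxuB: A0AR1W2X9
uxuA:
kdgK:
kdgA:
6pgd: A0A0R1WAU7
gntK: A0A0R1W2R7 A0A0R1W6K8
araD: A0A0R1W2Q5
xpkA: A0AR1W2X8
gapDH: A0A0R1WD78 A0A0R1W347
pgk: A0A0R1W7B1
pgam: A0A0R1WBW2 A0A0R1W3N5 A0A0R1W8P2 A0A0R1W2R9 A0A0R1W2L2 A0A0R1VYX3 A0A0R1W2D7
eno: A0A0R1W6P1
pyk: A0A0R1W3H0
ldh: A0AR1W2X2 A0A0R1W2M1
pdh: A0A0R1W4W0 A0A0R1W442 A0A0R1W4J5 A0A0R1WEK4
pta: A0A0R1W6L8
ackA: A0A0R1VTZ1
pntAB: A0A0R1W642 A0A0R1WE53 A0A0R1W6T3
nox: A0A0R1WBZ1
mak [candidate]: A0A0R1W2R7 A0A0R1W6K8
mpe [candidate]: A0A0R1W1H9
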