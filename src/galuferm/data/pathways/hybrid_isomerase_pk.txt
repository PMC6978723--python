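# pathway: hybrid_isomerase_pk
# Hybrid isomerase-phosphoketolase route: the upper isomerase reactions to
# mannonate are joined to the phosphoketolase pathway by a mannonate kinase
# and a 6-phosphomannonate 2-epimerase. With NADPH-linked fructuronate
# reductase matching NADP+-linked 6-phosphogluconate dehydrogenase, the
# conversion of galacturonate to ribulose-5-P + CO2 is redox-cofactor
# neutral; the full route yields equimolar lactate, acetate and CO2.
# substrate: galua
# externals: galua lactate acetate co2
# columns: id | enzyme | EC | equation | rev/irr | evidence keys
UxaC | uronate isomerase              | 5.3.1.12 | galua -> taga            | rev | uxaC
UxuE | tagaturonate 3-epimerase       | 5.1.2.7  | taga -> frua             | rev | uxaE
UxuB | fructuronate reductase         | 1.1.1.57 | frua + NAD(P)H -> manna  | irr | uxuB
MAK  | mannonate kinase               | -        | manna + ATP -> mann6p    | irr | mak?
MPE  | 6-phosphomannonate 2-epimerase | -        | mann6p -> pg6            | rev | mpe?
PGD  | 6-phosphogluconate dehydrogenase (decarboxylating) | 1.1.1.44 | pg6 -> ru5p + co2 + NADPH | irr | 6pgd
RPE  | ribulose-5-phosphate epimerase | 5.1.3.4  | ru5p -> xu5p             | rev | araD
XpkA | xylulose-5-phosphate phosphoketolase | 4.1.2.9 | xu5p -> gap + acp   | irr | xpkA
GAPDH | glyceraldehyde-3-P dehydrogenase | 1.2.1.12 | gap -> bpg13 + NADH   | irr | gapDH
PGK  | phosphoglycerate kinase        | 2.7.2.3  | bpg13 -> pg3 + ATP       | irr | pgk
PGM  | phosphoglycerate mutase        | 5.4.2.11 | pg3 -> pg2               | rev | pgam
ENO  | enolase                        | 4.2.1.11 | pg2 -> pep               | rev | eno
PYK  | pyruvate kinase                | 2.7.1.40 | pep -> pyr + ATP         | irr | pyk
nLDH | D-/L-lactate dehydrogenase     | 1.1.1.27 | pyr + NADH -> lactate    | irr | ldh
AckA | acetate kinase                 | 2.7.2.1  | acp -> acetate + ATP     | irr | ackA
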