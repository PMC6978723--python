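# pathway: canonical_isomerase
# The canonical (adapted Entner-Doudoroff) isomerase route for fermentative
# D-galacturonate catabolism, via the tagaturonate-3-epimerase branch
# (UxuE/UxuB/UxuA), KDG/KDPG and lower glycolysis to lactate.
# substrate: galua
# externals: galua lactate
# columns: id | enzyme | EC | equation | rev/irr | evidence keys
UxaC | uronate isomerase              | 5.3.1.12 | galua -> taga            | rev | uxaC
UxuE | tagaturonate 3-epimerase       | 5.1.2.7  | taga -> frua             | rev | uxaE
UxuB | fructuronate reductase         | 1.1.1.57 | frua + NAD(P)H -> manna  | irr | uxuB
UxuA | mannonate dehydratase          | 4.2.1.8  | manna -> kdg             | irr | uxuA
KdgK | 2-keto-3-deoxygluconate kinase | 2.7.1.45 | kdg + ATP -> kdpg        | irr | kdgK
KdgA | KDPG aldolase                  | 4.1.2.14 | kdpg -> pyr + gap        | irr | kdgA
GAPDH | glyceraldehyde-3-P dehydrogenase | 1.2.1.12 | gap -> bpg13 + NADH   | irr | gapDH
PGK  | phosphoglycerate kinase        | 2.7.2.3  | bpg13 -> pg3 + ATP       | irr | pgk
PGM  | phosphoglycerate mutase        | 5.4.2.11 | pg3 -> pg2               | rev | pgam
ENO  | enolase                        | 4.2.1.11 | pg2 -> pep               | rev | eno
PYK  | pyruvate kinase                | 2.7.1.40 | pep -> pyr + ATP         | irr | pyk
nLDH | D-/L-lactate dehydrogenase     | 1.1.1.27 | pyr + NADH -> lactate    | irr | ldh
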