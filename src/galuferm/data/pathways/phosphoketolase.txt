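# pathway: phosphoketolase
# The heterolactic phosphoketolase pathway proper, entered at
# 6-phosphogluconate: oxidative decarboxylation to ribulose-5-P, epimerase,
# phosphoketolase split to GAP + acetyl-P, lower glycolysis to lactate and
# acetate kinase to acetate.
# substrate: pg6
# externals: pg6 lactate acetate co2
# columns: id | enzyme | EC | equation | rev/irr | evidence keys
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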