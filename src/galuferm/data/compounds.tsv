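# galuferm compound registry v1
# columns: id <TAB> name <TAB> formula [<TAB> pseudo]
# Organic acids are neutral (fully protonated); phosphorylated species carry
# the HPO3 phosphoryl group. accoa is the acetyl moiety only (CoA implicit).
galua	D-galacturonate	C6H10O7
taga	D-tagaturonate	C6H10O7
frua	D-fructuronate	C6H10O7
manna	D-mannonate	C6H12O7
gluconate	D-gluconate	C6H12O7
glucose	D-glucose	C6H12O6
kdg	2-keto-3-deoxygluconate	C6H10O6
kdpg	2-keto-3-deoxy-6-phosphogluconate	C6H11O9P
mann6p	6-phosphomannonate	C6H13O10P
pg6	6-phosphogluconate	C6H13O10P
ru5p	ribulose-5-phosphate	C5H11O8P
xu5p	xylulose-5-phosphate	C5H11O8P
gap	glyceraldehyde-3-phosphate	C3H7O6P
bpg13	1,3-bisphosphoglycerate	C3H8O10P2
pg3	3-phosphoglycerate	C3H7O7P
pg2	2-phosphoglycerate	C3H7O7P
pep	phosphoenolpyruvate	C3H5O6P
pyr	pyruvate	C3H4O3
lactate	lactate	C3H6O3
acetate	acetate	C2H4O2
accoa	acetyl-CoA (acetyl moiety)	C2H2O	pseudo
acp	acetyl-phosphate	C2H5O5P
co2	carbon dioxide	CO2
h2o	water	H2O
nh3	ammonia	NH3
biomass	biomass (per C-mol, ash-free)	CH1.8O0.5N0.2
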