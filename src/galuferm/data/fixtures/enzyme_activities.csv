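# Specific enzyme activities in cell extracts of galacturonate-grown
# L. suebicus LCV1 (D = 0.13 1/h, 30 C, pH 4), umol (mg protein)^-1 min^-1,
# transcribed from the published activity table.
# Note: the running text gives the NADPH-linked fructuronate-reductase
# activity as 0.2 +/- 0.01 while the table prints 0.24 +/- 0.1; this file
# transcribes the table. No computation in this package depends on the value.
enzyme,abbrev,cofactor,substrate,activity,mean_dev
Fructuronate reductase,UxuB,NADPH,tagaturonate,0.24,0.1
Fructuronate reductase,UxuB,NADH,tagaturonate,0.99,0.1
Gluconate kinase,GntK,ATP+NADP+,mannonate,0.08,0.0
6-phosphogluconate dehydrogenase,6PGD,NADP+,6-phosphogluconate,1.18,0.1
Lactate dehydrogenase,nLDH,NADH,pyruvate,5.80,0.7
NADH oxidase,NOX,NADH,oxygen,0.19,0.0
Pyruvate dehydrogenase,PDH,NAD+,pyruvate,0.05,0.0
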