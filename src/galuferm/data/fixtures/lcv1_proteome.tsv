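# Proteins identified by shotgun proteomics in D-galacturonate-grown
# L. suebicus LCV1 (detection-only transcription of the published gene/
# protein table; normalized spectral counts were reported graphically only
# and are not part of this fixture).
protein_id
A0A0R1WA62
A0A0R1WAR4
A0A0R1W3Z7
A0AR1W2X9
A0A0R1WAU7
A0A0R1W2R7
A0A0R1W6K8
A0A0R1W2Q5
A0AR1W2X8
A0A0R1WD78
A0A0R1W347
A0A0R1W7B1
A0A0R1WBW2
A0A0R1W3N5
A0A0R1W8P2
A0A0R1W2R9
A0A0R1W2L2
A0A0R1VYX3
A0A0R1W2D7
A0A0R1W6P1
A0A0R1W3H0
A0AR1W2X2
A0A0R1W2M1
A0A0R1W4W0
A0A0R1W442
A0A0R1W4J5
A0A0R1WEK4
A0A0R1W6L8
A0A0R1VTZ1
A0A0R1W642
A0A0R1WE53
A0A0R1W6T3
A0A0R1WBZ1
A0A0R1W1H9
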