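# Biomass-specific conversion rates of anaerobic, D-galacturonate-limited
# chemostat cultures of L. suebicus LCV1 (D = 0.13 1/h, pH 4, 30 C);
# means of replicate steady states, transcribed from the published table.
compound_id,rate,unit
galua,-6.9,mmol/g/h
acetate,6.0,mmol/g/h
lactate,5.2,mmol/g/h
co2,7.2,mmol/g/h
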