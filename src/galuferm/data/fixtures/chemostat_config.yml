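# Sidecar configuration for chemostat_rates.csv
dilution_rate: 0.13        # 1/h
substrate_id: galua
biomass_formula: CH1.8O0.5N0.2
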