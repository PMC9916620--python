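quantity,value
spinosad_urban_pounds_2014,2608
spinosad_urban_micrograms_2014,1183052498279
spinosad_contact_ld50_ug_per_bee,0.0029
urban_acres,552724
urban_load_doses_per_acre,1500895028
pomegranate_load_doses_per_acre,2220400221
urban_resistance_anchor,8
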